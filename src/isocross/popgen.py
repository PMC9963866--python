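"""SNP genotype matrices, site filtering, Nei distance and NJ trees.

The pipeline starts from a VCF with per-genotype depth. Sites are
filtered with a fixed cascade (genotype depth >= 10, no missing calls, no
monomorphic sites, per-site heterozygous fraction <= 0.80, >= 20 bp
thinning), distances use Nei's (1972) standard genetic distance on
per-sample allele frequencies {0, 1/2, 1}, and the tree is built with
canonical Saitou-Nei neighbor joining plus locus-resampling bootstrap.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AnalysisError, ValidationError

logger = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: distance reported when two samples share no alleles at any locus
#: (Nei's I = 0, D infinite)
NEI_INF_SENTINEL = 999.0


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls (samples x loci) with per-genotype depth.

    ``calls`` uses the codes HOM_REF=0, HET=1, HOM_ALT=2, MISSING=-1.
    Loci are kept sorted by (chromosome, position). ``pseudodiploid``
    flags samples whose polyploid genotypes were collapsed so that any
    heterozygous class scores as a single het.
    """

    samples: list[str]
    chrom: np.ndarray  # str per locus
    pos: np.ndarray  # 1-based int per locus
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray  # int8, samples x loci
    depth: np.ndarray  # int32, samples x loci
    pseudodiploid: frozenset[str] = frozenset()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.calls.shape != (len(self.samples), len(self.pos)):
            raise AnalysisError("calls shape does not match samples x loci")
        self._sort_loci()

    def _sort_loci(self) -> None:
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        for name in ("chrom", "pos", "ref", "alt"):
            setattr(self, name, np.asarray(getattr(self, name))[order])
        self.calls = self.calls[:, order]
        self.depth = self.depth[:, order]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted (or resampled) to the given locus index."""
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref)[index],
            alt=np.asarray(self.alt)[index],
            calls=self.calls[:, index],
            depth=self.depth[:, index],
            pseudodiploid=self.pseudodiploid,
        )

    def allele_frequencies(self) -> np.ndarray:
        """Per-sample alt-allele frequency in {0, .5, 1}; NaN where missing."""
        freq = self.calls.astype(float) / 2.0
        freq[self.calls == MISSING] = np.nan
        return freq


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise AnalysisError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise AnalysisError("distance matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        index = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(index, index)])

    def to_tsv(self, path: str | Path, phylip_header: bool = False) -> None:
        with open(path, "w") as out:
            if phylip_header:
                out.write(f"{len(self.labels)}\n")
            else:
                out.write("label\t" + "\t".join(self.labels) + "\n")
            for i, label in enumerate(self.labels):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                out.write(f"{label}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            labels = header[1:]
            rows = []
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) if x != "NA" else np.nan for x in parts[1:]])
        return cls(labels, np.asarray(rows))


# ---------------------------------------------------------------------------
# VCF I/O


def read_genotypes(
    path: str | Path,
    samples: Sequence[str] | None = None,
    pseudodiploid: Iterable[str] = (),
    allow_no_depth: bool = False,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (counts logged). Depth
    is taken from FORMAT/DP, falling back to the sum of FORMAT/AD; a
    record without either raises unless ``allow_no_depth`` (depth then
    recorded as 0 and the depth filter must be disabled downstream).
    Samples named in ``pseudodiploid`` may carry genotypes of any ploidy;
    any mixed-allele genotype is scored as a single het.
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    pseudodiploid = frozenset(pseudodiploid)
    with pysam.VariantFile(str(path)) as vcf:
        all_samples = list(vcf.header.samples)
        if samples is None:
            samples = all_samples
        else:
            unknown = [s for s in samples if s not in all_samples]
            if unknown:
                raise ValidationError(f"samples not in VCF: {unknown}")
            samples = list(samples)
        chrom, pos, ref, alt = [], [], [], []
        call_rows, depth_rows = [], []
        skipped_multiallelic = skipped_non_snp = 0
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped_multiallelic += 1
                continue
            if len(rec.ref) != 1 or len(alts[0]) != 1 or alts[0] not in "ACGT":
                skipped_non_snp += 1
                continue
            calls = np.empty(len(samples), dtype=np.int8)
            depths = np.zeros(len(samples), dtype=np.int32)
            for k, name in enumerate(samples):
                sample = rec.samples[name]
                gt = sample.get("GT")
                alleles = [a for a in (gt or ()) if a is not None]
                if not alleles or (gt is not None and any(a is None for a in gt)):
                    calls[k] = MISSING
                elif all(a == 0 for a in alleles):
                    calls[k] = HOM_REF
                elif all(a == 1 for a in alleles):
                    calls[k] = HOM_ALT
                else:
                    calls[k] = HET  # pseudodiploid scoring: any mixed class
                if len(alleles) > 2 and name not in pseudodiploid:
                    raise ValidationError(
                        f"sample {name} has ploidy {len(alleles)} at "
                        f"{rec.chrom}:{rec.pos} but is not flagged pseudodiploid"
                    )
                dp = sample.get("DP")
                if dp is None:
                    ad = sample.get("AD")
                    if ad is not None:
                        dp = int(sum(a for a in ad if a is not None))
                    elif allow_no_depth:
                        dp = 0
                    else:
                        raise ValidationError(
                            f"no DP or AD for sample {name} at {rec.chrom}:{rec.pos}; "
                            "pass allow_no_depth=True to accept"
                        )
                depths[k] = int(dp)
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(alts[0])
            call_rows.append(calls)
            depth_rows.append(depths)
    logger.info(
        "read %d SNP loci (%d multiallelic, %d non-SNP skipped) for %d samples",
        len(pos), skipped_multiallelic, skipped_non_snp, len(samples),
    )
    n_loci = len(pos)
    gm = GenotypeMatrix(
        samples=list(samples),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        calls=np.asarray(call_rows, dtype=np.int8).T.reshape(len(samples), n_loci),
        depth=np.asarray(depth_rows, dtype=np.int32).T.reshape(len(samples), n_loci),
        pseudodiploid=pseudodiploid,
    )
    gm.meta["skipped_multiallelic"] = skipped_multiallelic
    gm.meta["skipped_non_snp"] = skipped_non_snp
    return gm


_GT_TEXT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal plain-text VCF (GT:DP)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for contig in sorted(set(gm.chrom.astype(str))):
            mask = gm.chrom.astype(str) == contig
            length = int(gm.pos[mask].max()) + 1000 if mask.any() else 1000
            out.write(f"##contig=<ID={contig},length={length}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples) + "\n"
        )
        for j in range(gm.n_loci):
            cells = [
                f"{_GT_TEXT[int(gm.calls[i, j])]}:{int(gm.depth[i, j])}"
                for i in range(gm.n_samples)
            ]
            out.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t.\tPASS\t.\t"
                "GT:DP\t" + "\t".join(cells) + "\n"
            )


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Loci x samples TSV of call codes (-1/0/1/2)."""
    with open(path, "w") as out:
        out.write("chrom\tpos\tref\talt\t" + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_loci):
            row = "\t".join(str(int(gm.calls[i, j])) for i in range(gm.n_samples))
            out.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.ref[j]}\t{gm.alt[j]}\t{row}\n")


# ---------------------------------------------------------------------------
# Filtering and summaries


def filter_sites(
    gm: GenotypeMatrix,
    min_depth: int = 10,
    max_het: float = 0.80,
    thin_bp: int = 20,
) -> GenotypeMatrix:
    """Apply the site-filtering cascade; per-step counts go to ``meta``.

    Order: (1) calls with depth < ``min_depth`` become missing; (2) sites
    with any missing call are dropped; (3) monomorphic sites are dropped;
    (4) sites with heterozygous fraction > ``max_het`` are dropped;
    (5) per-chromosome greedy left-to-right thinning keeps a site only if
    it lies >= ``thin_bp`` beyond the last kept site.
    """
    calls = gm.calls.copy()
    stats: dict[str, int] = {"input_sites": gm.n_loci}
    if min_depth > 0:
        low = (gm.depth < min_depth) & (calls != MISSING)
        calls[low] = MISSING
        stats["genotypes_set_missing_low_depth"] = int(low.sum())
    keep = ~np.any(calls == MISSING, axis=0)
    stats["removed_missing"] = int((~keep).sum())

    hom_ref = np.all(calls == HOM_REF, axis=0)
    hom_alt = np.all(calls == HOM_ALT, axis=0)
    mono = (hom_ref | hom_alt) & keep
    stats["removed_monomorphic"] = int(mono.sum())
    keep &= ~mono

    with np.errstate(invalid="ignore"):
        het_fraction = np.mean(calls == HET, axis=0)
    too_het = (het_fraction > max_het) & keep
    stats["removed_heterozygous"] = int(too_het.sum())
    keep &= ~too_het

    thinned = 0
    if thin_bp > 0:
        index = np.where(keep)[0]
        last_kept: dict[str, int] = {}
        for j in index:
            contig = str(gm.chrom[j])
            last = last_kept.get(contig)
            if last is not None and gm.pos[j] - last < thin_bp:
                keep[j] = False
                thinned += 1
            else:
                last_kept[contig] = int(gm.pos[j])
    stats["removed_thinning"] = thinned
    stats["output_sites"] = int(keep.sum())
    if stats["output_sites"] == 0:
        warnings.warn("all sites removed by the filter cascade")
    for step, count in stats.items():
        logger.info("filter %s: %d", step, count)
    out = GenotypeMatrix(
        samples=list(gm.samples),
        chrom=gm.chrom[keep],
        pos=gm.pos[keep],
        ref=np.asarray(gm.ref)[keep],
        alt=np.asarray(gm.alt)[keep],
        calls=calls[:, keep],
        depth=gm.depth[:, keep],
        pseudodiploid=gm.pseudodiploid,
    )
    out.meta["filter_stats"] = stats
    return out


def sample_heterozygosity(gm: GenotypeMatrix) -> dict[str, float]:
    """Fraction of heterozygous calls among non-missing calls per sample."""
    if gm.n_loci == 0:
        raise AnalysisError("empty genotype matrix")
    out = {}
    for i, name in enumerate(gm.samples):
        called = gm.calls[i] != MISSING
        if not called.any():
            warnings.warn(f"sample {name} has no called genotypes")
            out[name] = float("nan")
        else:
            out[name] = float(np.mean(gm.calls[i][called] == HET))
    return out


# ---------------------------------------------------------------------------
# Nei's standard genetic distance


def nei_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Nei's (1972) standard genetic distance between samples.

    Per locus with frequencies x, y of the alt allele: j_x = x^2+(1-x)^2,
    j_y likewise, j_xy = xy+(1-x)(1-y). J terms are arithmetic means over
    loci, I = J_xy / sqrt(J_x J_y) and D = -ln I. Loci missing in either
    member of a pair are excluded pairwise. I numerically above 1 is
    clamped with a warning; I = 0 yields the ``NEI_INF_SENTINEL``.
    """
    if gm.n_samples < 2 or gm.n_loci < 1:
        raise AnalysisError("need >= 2 samples and >= 1 locus")
    freq = gm.allele_frequencies()
    n = gm.n_samples
    values = np.zeros((n, n))
    homo = freq**2 + (1 - freq) ** 2  # per sample x locus
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(freq[i]) & ~np.isnan(freq[j])
            if not shared.any():
                raise AnalysisError(
                    f"samples {gm.samples[i]} and {gm.samples[j]} share no called loci"
                )
            x, y = freq[i][shared], freq[j][shared]
            jx = float(np.mean(homo[i][shared]))
            jy = float(np.mean(homo[j][shared]))
            jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
            identity = jxy / math.sqrt(jx * jy)
            if identity > 1.0:
                if identity > 1.0 + 1e-9:
                    warnings.warn(
                        f"Nei identity {identity} > 1 for pair "
                        f"({gm.samples[i]}, {gm.samples[j]}); clamped"
                    )
                identity = 1.0
            if identity <= 0.0:
                warnings.warn(
                    f"no shared alleles for ({gm.samples[i]}, {gm.samples[j]}); "
                    "reporting sentinel distance"
                )
                d = NEI_INF_SENTINEL
            else:
                d = -math.log(identity)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(gm.samples), values)


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class TreeNode:
    """Node of an (unrooted) phylogeny, stored rooted at a trifurcation."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # percent, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree over a label set with optional bootstrap supports."""

    root: TreeNode
    labels: list[str]
    n_bootstrap: int = 0

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Pairwise path lengths between leaves."""
        dist: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child, length in node.children:
                sub = walk(child)
                below.append({leaf: d + length for leaf, d in sub.items()})
            for a in range(len(below)):
                for b in range(a + 1, len(below)):
                    for la, da in below[a].items():
                        for lb, db in below[b].items():
                            key = (min(la, lb), max(la, lb))
                            dist[key] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return dist

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller/canonical leaf side)."""
        total = frozenset(self.labels)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    side = frozenset(child.leaves())
                    if 1 < len(side) < len(total) - 1:
                        out.add(_canonical_side(side, total))
                    walk(child)

        walk(self.root)
        return out

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                text = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = f"{node.support:g}"
                text = f"({inner}){label}"
            if length is not None:
                text += f":{length:.10g}"
            return text

        return fmt(self.root, None) + ";"


def _canonical_side(side: frozenset[str], total: frozenset[str]) -> frozenset[str]:
    other = total - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: sorted(s))


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j with ties
    broken by the lexicographically smallest (label, label) pair, where a
    cluster is labeled by its smallest leaf name. Negative branch lengths
    are clamped to zero with the difference moved to the sibling edge.
    """
    n = len(dm.labels)
    if n < 3:
        raise AnalysisError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm.values).any():
        raise AnalysisError("distance matrix contains NaN")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    labels = list(dm.labels)  # tie-break label per active cluster
    d = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_label = tuple(sorted((labels[i], labels[j])))
                key = (q, pair_label)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
            logger.debug("negative NJ branch clamped (moved to sibling)")
        if lj < 0:
            li += lj
            lj = 0.0
            logger.debug("negative NJ branch clamped (moved to sibling)")
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # reuse slot i for the new cluster
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = sorted(active, key=lambda idx: labels[idx])
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    lengths = [li, lj, lk]
    order = [i, j, k]
    # clamp any negative terminal length, moving the excess to the others
    for idx in range(3):
        if lengths[idx] < 0:
            deficit = lengths[idx]
            lengths[idx] = 0.0
            for other in range(3):
                if other != idx:
                    lengths[other] += deficit / 2.0
            logger.debug("negative NJ branch clamped at final join")
    root = TreeNode(children=[(nodes[x], lengths[p]) for p, x in enumerate(order)])
    return PhyloTree(root=root, labels=sorted(dm.labels))


def bootstrap_tree(
    gm: GenotypeMatrix,
    n_reps: int = 1000,
    seed: int | None = None,
    min_depth: int = 0,
    distance_fn=nei_distance,
) -> PhyloTree:
    """NJ tree with locus-resampling bootstrap supports (percent).

    The full-data tree is returned with each internal node annotated by
    the percentage of replicates whose tree contains the same
    bipartition. Replicates with a degenerate (all-zero) distance matrix
    are skipped and the denominator adjusted. ``seed`` is required
    whenever ``n_reps > 0``.
    """
    full_dm = distance_fn(gm)
    tree = nj_tree(full_dm)
    if n_reps == 0:
        return tree
    if seed is None:
        raise ValidationError("a seed is required for the bootstrap")
    rng = np.random.default_rng(seed)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    total = frozenset(tree.labels)
    used = 0
    skipped = 0
    for _ in range(n_reps):
        index = rng.integers(0, gm.n_loci, size=gm.n_loci)
        rep = gm.take_loci(np.sort(index))
        try:
            rep_dm = distance_fn(rep)
        except AnalysisError:
            skipped += 1
            continue
        off = rep_dm.values[np.triu_indices(len(rep_dm.labels), k=1)]
        if np.all(off == 0):
            skipped += 1
            continue
        rep_tree = nj_tree(rep_dm)
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
        used += 1
    if skipped:
        logger.info("bootstrap: %d degenerate replicates skipped", skipped)
    if used == 0:
        raise AnalysisError("all bootstrap replicates degenerate")

    def annotate(node: TreeNode) -> None:
        for child, _ in node.children:
            if not child.is_leaf:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(total) - 1:
                    bp = _canonical_side(side, total)
                    child.support = 100.0 * counts[bp] / used
                annotate(child)

    annotate(tree.root)
    tree.n_bootstrap = used
    return tree
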