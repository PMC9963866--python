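"""Ground-truth synthetic data: species trees, genotypes and diallels.

Taxa diverge along a known tree; biallelic loci accumulate substitutions
as Poisson events on branches and taxa are rendered as near-homozygous
individuals (optionally with F1 hybrids carrying one allele from each
parent). Diallel cross outcomes are drawn from a per-stage barrier model
in which barrier strength is a monotone function of pairwise tree
distance, so each stage's expected RI equals its barrier strength by
construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .crossdata import CrossRecord
from .errors import ValidationError
from .popgen import (
    HET,
    HOM_ALT,
    HOM_REF,
    GenotypeMatrix,
    PhyloTree,
    TreeNode,
    write_vcf,
)

logger = logging.getLogger(__name__)

STAGE_KEYS = ("pollen_pistil", "fruit_set", "fruit_weight", "seed_viability", "germination")

BarrierMap = Callable[[float], Mapping[str, float]]


def linear_barrier_map(max_distance: float, ceiling: float = 0.95) -> BarrierMap:
    """Barriers rise linearly with distance, capped below 1."""

    def fn(distance: float) -> dict[str, float]:
        b = min(ceiling, max(0.0, distance / max_distance * ceiling))
        return {key: b for key in STAGE_KEYS}

    return fn


def constant_barrier_map(level: float = 0.0) -> BarrierMap:
    """Distance-independent barriers (null model)."""
    if not 0.0 <= level <= 1.0:
        raise ValidationError("barrier level must be in [0, 1]")

    def fn(distance: float) -> dict[str, float]:
        return {key: level for key in STAGE_KEYS}

    return fn


@dataclass
class SynthConfig:
    n_taxa: int = 6
    n_loci: int = 2000
    # caterpillar default: a balanced shape yields too few distinct pairwise
    # distances for permutation tests to resolve
    tree_shape: str = "caterpillar"
    branch_scale: float = 0.02  # expected substitutions per locus per unit length
    barrier_map: BarrierMap = field(default_factory=lambda: linear_barrier_map(8.0))
    residual_heterozygosity: float = 0.004
    depth_mean: float = 30.0
    depth_shape: float = 10.0  # negative-binomial dispersion
    n_crosses_per_pair: int = 25
    n_pollentube_per_pair: int = 5
    asymmetry: float = 0.0  # sd of per-direction logit perturbation of barriers
    make_f1: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_loci < 1:
            raise ValidationError("counts must be positive (>= 2 taxa, >= 1 locus)")
        if self.n_crosses_per_pair < 1 or self.n_pollentube_per_pair < 1:
            raise ValidationError("per-pair replicate counts must be positive")
        if self.tree_shape not in ("balanced", "caterpillar", "random"):
            raise ValidationError(f"unknown tree_shape: {self.tree_shape!r}")


@dataclass
class SynthTruth:
    """Everything the simulator knows: tree, distances, barriers, baselines."""

    tree: PhyloTree
    taxa: list[str]
    distances: np.ndarray  # pairwise tree path lengths, taxa order
    barriers: dict[tuple[str, str], dict[str, float]]  # per directed pair
    baselines: dict[str, dict[str, float]]  # per-taxon selfing performance

    def distance(self, a: str, b: str) -> float:
        return float(self.distances[self.taxa.index(a), self.taxa.index(b)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "taxa": self.taxa,
            "tree_newick": self.tree.to_newick(include_support=False),
            "distances": self.distances.tolist(),
            "barriers": {f"{f}x{m}": dict(b) for (f, m), b in sorted(self.barriers.items())},
            "baselines": self.baselines,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _taxon_names(n: int) -> list[str]:
    return [f"T{str(i + 1).zfill(2)}" for i in range(n)]


def build_tree(cfg: SynthConfig, rng: np.random.Generator) -> PhyloTree:
    """Species tree with unit-ish branch lengths for the chosen shape.

    Topology depends only on ``tree_shape`` and ``n_taxa`` except for the
    ``random`` shape, which consumes the generator.
    """
    names = _taxon_names(cfg.n_taxa)
    nodes = [TreeNode(name=n) for n in names]
    lengths = {id(n): 1.0 for n in nodes}
    if cfg.tree_shape == "caterpillar":
        pending = list(nodes)
        while len(pending) > 3:
            a = pending.pop(0)
            b = pending.pop(0)
            parent = TreeNode(children=[(a, lengths[id(a)]), (b, lengths[id(b)])])
            lengths[id(parent)] = 1.0
            pending.insert(0, parent)
    elif cfg.tree_shape == "balanced":
        pending = list(nodes)
        while len(pending) > 3:
            nxt = []
            k = 0
            while k + 1 < len(pending):
                a, b = pending[k], pending[k + 1]
                parent = TreeNode(children=[(a, lengths[id(a)]), (b, lengths[id(b)])])
                lengths[id(parent)] = 1.0
                nxt.append(parent)
                k += 2
            if k < len(pending):
                nxt.append(pending[k])
            pending = nxt
    else:  # random
        pending = list(nodes)
        while len(pending) > 3:
            i, j = sorted(rng.choice(len(pending), size=2, replace=False))
            b = pending.pop(j)
            a = pending.pop(i)
            parent = TreeNode(children=[(a, lengths[id(a)]), (b, lengths[id(b)])])
            lengths[id(parent)] = 1.0
            pending.append(parent)
    if len(pending) == 1:
        root = pending[0]
    else:
        root = TreeNode(children=[(n, lengths[id(n)]) for n in pending])
    return PhyloTree(root=root, labels=sorted(names))


def _branches(tree: PhyloTree) -> list[tuple[TreeNode, float, list[str]]]:
    """(node, branch length to parent, leaves below) for every non-root node."""
    out = []

    def walk(node: TreeNode) -> None:
        for child, length in node.children:
            out.append((child, length, sorted(child.leaves())))
            walk(child)

    walk(tree.root)
    return out


def simulate_genotypes(cfg: SynthConfig) -> tuple[GenotypeMatrix, SynthTruth]:
    """Genotype matrix of near-homozygous taxa diverged along the tree.

    Each locus starts from the reference allele at the root; substitution
    events are Poisson on each branch (rate = branch_scale x length /
    n_loci per locus, i.e. branch_scale expected substitutions per unit
    length across the locus panel) and flip the allele state of every
    taxon below the branch. Residual heterozygosity converts a small
    fraction of calls to hets; depths are negative-binomial.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = build_tree(cfg, rng)
    names = _taxon_names(cfg.n_taxa)
    leaf_dist = tree.leaf_distances()
    n = cfg.n_taxa
    distances = np.zeros((n, n))
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            b = names[j]
            distances[i, j] = distances[j, i] = leaf_dist[(min(a, b), max(a, b))]

    # haplotype per taxon: 0 = ancestral/ref, 1 = derived/alt
    hap = np.zeros((n, cfg.n_loci), dtype=np.int8)
    index = {name: k for k, name in enumerate(names)}
    saturated = 0
    for _, length, below in _branches(tree):
        # branch_scale is the per-locus substitution rate per unit length
        flips = rng.poisson(cfg.branch_scale * length * cfg.n_loci)
        if flips > cfg.n_loci:
            saturated += 1
            flips = cfg.n_loci
        sites = rng.choice(cfg.n_loci, size=flips, replace=False)
        rows = [index[t] for t in below]
        hap[np.ix_(rows, sites)] ^= 1
    if saturated:
        warnings.warn(f"{saturated} branches saturated (more substitutions than loci)")

    calls = np.where(hap == 1, HOM_ALT, HOM_REF).astype(np.int8)
    het_mask = rng.random(calls.shape) < cfg.residual_heterozygosity
    calls[het_mask] = HET

    samples = list(names)
    if cfg.make_f1:
        for i in range(0, n - 1, 2):
            a, b = names[i], names[i + 1]
            f1 = np.where(hap[i] == hap[i + 1],
                          np.where(hap[i] == 1, HOM_ALT, HOM_REF), HET).astype(np.int8)
            calls = np.vstack([calls, f1])
            samples.append(f"F1_{a}x{b}")

    p = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
    depth = rng.negative_binomial(cfg.depth_shape, p, size=calls.shape).astype(np.int32)

    positions = np.sort(rng.choice(np.arange(1, cfg.n_loci * 60), size=cfg.n_loci, replace=False))
    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.asarray(["chr1"] * cfg.n_loci, dtype=object),
        pos=positions,
        ref=np.asarray(["A"] * cfg.n_loci, dtype=object),
        alt=np.asarray(["C"] * cfg.n_loci, dtype=object),
        calls=calls,
        depth=depth,
    )
    truth = SynthTruth(
        tree=tree,
        taxa=names,
        distances=distances,
        barriers=_draw_barriers(cfg, names, distances, np.random.default_rng(cfg.seed + 1)),
        baselines=_draw_baselines(names, np.random.default_rng(cfg.seed + 2)),
    )
    return gm, truth


def _draw_barriers(
    cfg: SynthConfig,
    names: Sequence[str],
    distances: np.ndarray,
    rng: np.random.Generator,
) -> dict[tuple[str, str], dict[str, float]]:
    barriers = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                barriers[(a, b)] = {key: 0.0 for key in STAGE_KEYS}
                continue
            base = dict(cfg.barrier_map(float(distances[i, j])))
            if cfg.asymmetry > 0:
                for key in STAGE_KEYS:
                    jitter = rng.normal(0.0, cfg.asymmetry)
                    base[key] = float(np.clip(base[key] + jitter, 0.0, 1.0))
            barriers[(a, b)] = base
    return barriers


def _draw_baselines(
    names: Sequence[str], rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    out = {}
    for name in names:
        out[name] = {
            "fruit_set": float(rng.uniform(0.5, 0.9)),
            "fruit_weight": float(rng.uniform(50.0, 200.0)),
            "seed_count": float(rng.uniform(20.0, 40.0)),
            "seed_weight_mg": float(rng.uniform(20.0, 60.0)),
            "germination": float(rng.uniform(0.7, 0.95)),
        }
    return out


def simulate_diallel(cfg: SynthConfig, truth: SynthTruth) -> list[CrossRecord]:
    """Cross records for the full diallel (reciprocals plus selfings).

    Per directed pair: ``n_pollentube_per_pair`` pollinations scored for
    pollen-tube progression with score ~ Binomial(4, 1 - b_pollen), and
    ``n_crosses_per_pair`` pollinations recorded for post-zygotic stages
    with fruit set ~ Bernoulli(s_self x (1 - b_fruit)), fruit weight
    normal around w_self x (1 - b_fruit_weight), seed count ~
    Poisson(lambda_self x (1 - b_seed)), and germination binomial with
    rate g_self x (1 - b_germ). Selfings use zero barriers, so the
    expected RI of each stage equals its barrier strength. A pair with
    b_pollen = 1 sets no fruit at all (complete pre-zygotic arrest).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    records: list[CrossRecord] = []
    for female in truth.taxa:
        for male in truth.taxa:
            b = truth.barriers[(female, male)]
            base = truth.baselines[female]
            for rep in range(cfg.n_pollentube_per_pair):
                score = int(rng.binomial(4, 1.0 - b["pollen_pistil"]))
                records.append(
                    CrossRecord(
                        female_taxon=female,
                        male_taxon=male,
                        replicate_id=f"pt{rep + 1}",
                        pollen_score=score,
                        ovules_fertilized=(score == 4),
                        fruit_set=False,
                    )
                )
            arrested = b["pollen_pistil"] >= 1.0
            for rep in range(cfg.n_crosses_per_pair):
                p_fruit = 0.0 if arrested else base["fruit_set"] * (1.0 - b["fruit_set"])
                fruit = bool(rng.random() < p_fruit)
                if not fruit:
                    records.append(
                        CrossRecord(
                            female_taxon=female,
                            male_taxon=male,
                            replicate_id=f"px{rep + 1}",
                            fruit_set=False,
                        )
                    )
                    continue
                weight = max(
                    0.0,
                    float(
                        rng.normal(
                            base["fruit_weight"] * (1.0 - b["fruit_weight"]),
                            0.05 * base["fruit_weight"],
                        )
                    ),
                )
                seeds = int(rng.poisson(base["seed_count"] * (1.0 - b["seed_viability"])))
                germinated = int(
                    rng.binomial(seeds, base["germination"] * (1.0 - b["germination"]))
                ) if seeds > 0 else 0
                seed_weight = float(rng.normal(base["seed_weight_mg"], 3.0)) if seeds else None
                records.append(
                    CrossRecord(
                        female_taxon=female,
                        male_taxon=male,
                        replicate_id=f"px{rep + 1}",
                        fruit_set=True,
                        fruit_weight=weight,
                        seed_count=seeds,
                        seed_weight=max(0.0, seed_weight) if seed_weight is not None else None,
                        seeds_sown=seeds,
                        seeds_germinated=germinated,
                    )
                )
    return records


def write_cross_records(records: Sequence[CrossRecord], path: str | Path) -> None:
    """Write records in the cross-record TSV schema (NA = missing)."""
    fields = [
        "female_taxon", "male_taxon", "replicate_id", "pollen_score",
        "ovules_fertilized", "fruit_set", "fruit_weight", "seed_count",
        "seed_weight", "seeds_sown", "seeds_germinated",
    ]
    with open(path, "w") as out:
        out.write("\t".join(fields) + "\n")
        for record in records:
            row = []
            for name in fields:
                value = getattr(record, name)
                if value is None:
                    row.append("NA")
                elif isinstance(value, bool):
                    row.append("1" if value else "0")
                elif isinstance(value, float):
                    row.append(f"{value:.6g}")
                else:
                    row.append(str(value))
            out.write("\t".join(row) + "\n")


def simulate_dataset(cfg: SynthConfig, out_dir: str | Path) -> dict[str, str]:
    """Emit a complete dataset directory: crosses.tsv, genotypes.vcf,
    truth.json. Returns the artifact paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gm, truth = simulate_genotypes(cfg)
    records = simulate_diallel(cfg, truth)
    paths = {
        "crosses": str(out_dir / "crosses.tsv"),
        "genotypes": str(out_dir / "genotypes.vcf"),
        "truth": str(out_dir / "truth.json"),
    }
    write_cross_records(records, paths["crosses"])
    write_vcf(gm, paths["genotypes"])
    truth.to_json(paths["truth"])
    logger.info("synthetic dataset written to %s", out_dir)
    return paths
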