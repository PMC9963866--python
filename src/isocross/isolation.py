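"""Stage-wise reproductive-isolation indices and sequential contributions.

Four stages act in fixed life-history order: pollen-pistil compatibility
(pre-zygotic), then fruit set, fruit weight and seed production
(post-zygotic). Per directed cross the stage *success* is the
interspecific value standardized by the seed parent's selfing value;
per-direction RI = max(0, 1 - success) and reciprocal directions are
averaged to one pair value. Absolute contributions follow the sequential
recurrence AC_n = RI_n * (1 - sum of earlier AC), total T = sum(AC) and
relative contributions RC_n = AC_n / T.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .crossdata import CrossSummary
from .errors import AnalysisError

logger = logging.getLogger(__name__)


class Stage(Enum):
    """Sequential isolation stages in life-history order."""

    POLLEN_PISTIL = "pollen_pistil"
    FRUIT_SET = "fruit_set"
    FRUIT_WEIGHT = "fruit_weight"
    SEED_VIABILITY = "seed_viability"  # seed set: formed seeds per mature fruit

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]

    def __lt__(self, other: "Stage") -> bool:
        return self.order < other.order


_STAGE_ORDER = {
    Stage.POLLEN_PISTIL: 0,
    Stage.FRUIT_SET: 1,
    Stage.FRUIT_WEIGHT: 2,
    Stage.SEED_VIABILITY: 3,
}

STAGES: tuple[Stage, ...] = tuple(sorted(_STAGE_ORDER, key=lambda s: _STAGE_ORDER[s]))

_STAGE_ATTR = {
    Stage.POLLEN_PISTIL: "mean_pollen_score",
    Stage.FRUIT_SET: "fruit_set_fraction",
    Stage.FRUIT_WEIGHT: "mean_fruit_weight",
    Stage.SEED_VIABILITY: "mean_seed_count",
}


@dataclass
class RIMatrix:
    """Symmetric per-pair RI values in [0, 1] for one stage (NaN = missing)."""

    stage: Stage
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise AnalysisError("RIMatrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise AnalysisError("RIMatrix must be symmetric")

    @property
    def n_pairs(self) -> int:
        iu = np.triu_indices(len(self.taxa), k=1)
        return int(np.sum(~np.isnan(self.values[iu])))

    def pair_values(self) -> dict[tuple[str, str], float]:
        """Present upper-triangle entries keyed by sorted taxon pair."""
        out = {}
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                v = self.values[i, j]
                if not np.isnan(v):
                    out[(self.taxa[i], self.taxa[j])] = float(v)
        return out

    def mean_ri(self) -> float:
        """Mean over assessable pairs."""
        values = list(self.pair_values().values())
        if not values:
            raise AnalysisError(f"no assessable pairs for stage {self.stage.value}")
        return float(np.mean(values))


@dataclass
class ContributionTable:
    """Sequential absolute/relative stage contributions and the total T."""

    stages: list[Stage]
    mean_ri: np.ndarray
    ac: np.ndarray
    rc: np.ndarray
    total: float
    n_per_stage: list[int] | None = None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("stage\tN\tmean_RI\tabsolute\trelative\n")
            for k, stage in enumerate(self.stages):
                n = self.n_per_stage[k] if self.n_per_stage else "NA"
                rc = "NA" if np.isnan(self.rc[k]) else f"{self.rc[k]:.6g}"
                out.write(
                    f"{stage.value}\t{n}\t{self.mean_ri[k]:.6g}\t{self.ac[k]:.6g}\t{rc}\n"
                )
            total_rc = "NA" if np.isnan(self.rc).any() else f"{self.rc.sum():.6g}"
            out.write(f"total\tNA\tNA\t{self.total:.6g}\t{total_rc}\n")


def stage_success(
    summary: CrossSummary, self_summary: CrossSummary, stage: Stage
) -> float | None:
    """Interspecific/selfing success ratio for one direction and stage.

    Returns ``None`` (unassessable) when either value is missing or the
    selfing baseline is zero; the ratio itself may exceed 1 (clamping is
    applied at the RI step, not here).
    """
    attr = _STAGE_ATTR[stage]
    value = getattr(summary, attr)
    baseline = getattr(self_summary, attr)
    if baseline is None or baseline == 0:
        return None
    if value is None:
        return None
    if stage in (Stage.FRUIT_WEIGHT, Stage.SEED_VIABILITY) and summary.fruit_set_fraction == 0:
        return None  # no fruit harvested in this direction
    return float(value) / float(baseline)


def ri_for_pair(success_ab: float | None, success_ba: float | None) -> float:
    """Pair RI: per-direction max(0, 1 - success), averaged over the
    assessable directions."""
    directions = [s for s in (success_ab, success_ba) if s is not None]
    if not directions:
        raise AnalysisError("both directions unassessable")
    return float(np.mean([max(0.0, 1.0 - s) for s in directions]))


def ri_matrix(
    summaries: Iterable[CrossSummary],
    stage: Stage,
    taxa: Sequence[str] | None = None,
) -> RIMatrix:
    """Build the symmetric per-pair RI matrix for one stage.

    Selfing summaries (diagonal of the diallel) provide the
    standardization baselines; pairs unassessable in both directions get
    NaN. For stages downstream of fruit set, a direction with zero fruit
    is unassessable, so a pair with no fruit in either direction is
    missing there while its fruit-set entry is 1.
    """
    by_pair: dict[tuple[str, str], CrossSummary] = {}
    for summary in summaries:
        by_pair[(summary.female_taxon, summary.male_taxon)] = summary
    if taxa is None:
        taxa = sorted({t for pair in by_pair for t in pair})
    taxa = list(taxa)
    selfs = {t: by_pair.get((t, t)) for t in taxa}
    missing_selfs = [t for t, s in selfs.items() if s is None]
    if missing_selfs:
        raise AnalysisError(f"no selfing summaries for: {missing_selfs}")
    n = len(taxa)
    values = np.full((n, n), np.nan)
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            b = taxa[j]
            successes = []
            for female, male in ((a, b), (b, a)):
                summary = by_pair.get((female, male))
                if summary is None:
                    successes.append(None)
                else:
                    successes.append(stage_success(summary, selfs[female], stage))
            if all(s is None for s in successes):
                continue
            values[i, j] = values[j, i] = ri_for_pair(*successes)
    return RIMatrix(stage=stage, taxa=taxa, values=values)


def sequential_contributions(
    mean_ri: Sequence[float],
    n_per_stage: Sequence[int] | None = None,
    stages: Sequence[Stage] | None = None,
) -> ContributionTable:
    """Sequential decomposition of total isolation over ordered stages.

    AC_1 = RI_1, AC_n = RI_n * (1 - sum of earlier AC), T = sum(AC) and
    RC_n = AC_n / T. With every RI in [0, 1] each AC is non-negative,
    T is in [0, 1] and 1 - T equals the product of (1 - RI_n).
    """
    ri = np.asarray(mean_ri, dtype=float)
    if ri.ndim != 1 or ri.size == 0:
        raise AnalysisError("mean_ri must be a non-empty 1-d sequence")
    if np.any((ri < 0) | (ri > 1)):
        raise AnalysisError("mean RI values must lie in [0, 1]")
    if stages is None:
        stages = list(STAGES[: ri.size]) if ri.size <= len(STAGES) else [
            Stage.POLLEN_PISTIL
        ] * ri.size
    ac = np.empty_like(ri)
    remaining = 1.0
    for k, value in enumerate(ri):
        ac[k] = value * remaining
        remaining -= ac[k]
    total = float(ac.sum())
    if total > 0:
        rc = ac / total
    else:
        warnings.warn("total isolation is 0; relative contributions undefined")
        rc = np.full_like(ac, np.nan)
    return ContributionTable(
        stages=list(stages),
        mean_ri=ri,
        ac=ac,
        rc=rc,
        total=total,
        n_per_stage=list(n_per_stage) if n_per_stage is not None else None,
    )


def contributions_from_ac(ac: Sequence[float]) -> ContributionTable:
    """Rebuild a full contribution table from absolute contributions.

    Inverts the sequential recurrence to recover the per-stage mean RI
    values (RI_n = AC_n / (1 - sum of earlier AC)) and re-runs the forward
    decomposition, so totals and relative columns are produced by the same
    engine as any other input.
    """
    ac = np.asarray(ac, dtype=float)
    ri = np.empty_like(ac)
    remaining = 1.0
    for k, value in enumerate(ac):
        if remaining <= 0:
            raise AnalysisError("absolute contributions already sum to >= 1")
        ri[k] = value / remaining
        remaining -= value
    return sequential_contributions(ri)


def contributions_from_matrices(
    matrices: Sequence[RIMatrix], per_pair: bool = False
) -> ContributionTable:
    """Contribution table from the four stage RI matrices.

    Default mode averages RI over each stage's assessable pairs first and
    feeds the stage means to the recurrence (stages may therefore rest on
    different pair sets). ``per_pair`` instead runs the recurrence per
    pair restricted to pairs assessable at every stage, then averages the
    per-pair AC columns.
    """
    matrices = sorted(matrices, key=lambda m: m.stage.order)
    if not per_pair:
        means = [m.mean_ri() for m in matrices]
        ns = [m.n_pairs for m in matrices]
        return sequential_contributions(means, ns, [m.stage for m in matrices])
    per_stage = [m.pair_values() for m in matrices]
    common = set(per_stage[0])
    for pairs in per_stage[1:]:
        common &= set(pairs)
    if not common:
        raise AnalysisError("no pair assessable at every stage")
    tables = [
        sequential_contributions([pairs[p] for pairs in per_stage])
        for p in sorted(common)
    ]
    ac = np.mean([t.ac for t in tables], axis=0)
    mean_ri = np.mean([t.mean_ri for t in tables], axis=0)
    total = float(ac.sum())
    rc = ac / total if total > 0 else np.full_like(ac, np.nan)
    return ContributionTable(
        stages=[m.stage for m in matrices],
        mean_ri=mean_ri,
        ac=ac,
        rc=rc,
        total=total,
        n_per_stage=[len(common)] * len(matrices),
    )


def write_ri_matrix(matrix: RIMatrix, path: str | Path, long_path: str | Path | None = None) -> None:
    """Write an RI matrix as square TSV (and optionally long format)."""
    with open(path, "w") as out:
        out.write("taxon\t" + "\t".join(matrix.taxa) + "\n")
        for i, taxon in enumerate(matrix.taxa):
            row = [taxon]
            for j in range(len(matrix.taxa)):
                v = matrix.values[i, j]
                row.append("NA" if (i == j or np.isnan(v)) else f"{v:.6g}")
            out.write("\t".join(row) + "\n")
    if long_path is not None:
        with open(long_path, "w") as out:
            out.write("taxon_a\ttaxon_b\tstage\tri\n")
            for (a, b), v in sorted(matrix.pair_values().items()):
                out.write(f"{a}\t{b}\t{matrix.stage.value}\t{v:.6g}\n")
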