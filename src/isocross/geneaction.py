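"""Degree-of-dominance estimation for traits measured on P1, P2 and F1.

d = mean(F1) - midparent, |a| = |mean(P1) - mean(P2)| / 2, and the
degree of dominance is d/|a|: 0 additive, +/-1 full dominance, beyond
+/-1 overdominance. Significance of the deviation from the midparent is
tested with the single-df contrast F1 - P1/2 - P2/2 = 0 against the
pooled within-class variance of a one-way fixed-effects layout.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, ValidationError

logger = logging.getLogger(__name__)

#: |d/a| band edges for additive / partial dominance / dominance /
#: overdominance; conventional quantitative-genetics cutoffs.
DEFAULT_THRESHOLDS = (0.25, 0.75, 1.25)


@dataclass(frozen=True)
class TraitSample:
    """Trait replicate measurements for one genotype class."""

    genotype_class: str  # P1 | P2 | F1
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.genotype_class not in ("P1", "P2", "F1"):
            raise ValidationError(
                f"genotype_class must be P1, P2 or F1, got {self.genotype_class!r}"
            )
        if len(self.values) < 1:
            raise ValidationError("at least one replicate value is required")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class GeneActionResult:
    mean_p1: float
    mean_p2: float
    mean_f1: float
    d: float
    a_abs: float
    ratio: float
    f_ratio: float
    p_value: float
    df_error: int
    classification: str  # additive | partial_dominance | dominance | overdominance
    toward: str  # P1 | P2 | neither


def classify_ratio(ratio: float, thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> str:
    t1, t2, t3 = thresholds
    magnitude = abs(ratio)
    if magnitude < t1:
        return "additive"
    if magnitude <= t2:
        return "partial_dominance"
    if magnitude <= t3:
        return "dominance"
    return "overdominance"


def gene_action(
    p1: TraitSample,
    p2: TraitSample,
    f1: TraitSample,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> GeneActionResult:
    """Estimate d, |a|, d/|a| and the midparent-contrast F test.

    The contrast L = mean(F1) - mean(P1)/2 - mean(P2)/2 is tested with
    SS = L^2 / sum(c_i^2 / n_i) on 1 df against the pooled error on
    N - 3 df. Location shifts leave everything unchanged; positive
    scaling leaves d/|a| and F unchanged.
    """
    groups = {"P1": p1, "P2": p2, "F1": f1}
    for name, sample in groups.items():
        if sample.genotype_class != name:
            raise ValidationError(f"argument {name} has class {sample.genotype_class}")
    mean_p1, mean_p2, mean_f1 = p1.mean, p2.mean, f1.mean
    d = mean_f1 - (mean_p1 + mean_p2) / 2.0
    a_abs = abs(mean_p1 - mean_p2) / 2.0

    if a_abs == 0:
        if d == 0:
            ratio = 0.0
        else:
            ratio = math.copysign(math.inf, d)
            warnings.warn("parents have equal means; d/|a| is infinite")
    else:
        ratio = d / a_abs

    n = [len(s.values) for s in (p1, p2, f1)]
    total_n = sum(n)
    df_error = total_n - 3
    if df_error < 1:
        raise AnalysisError("pooled error needs at least one df (>= 2 values in some class)")
    ss_within = sum(
        float(np.sum((np.asarray(s.values) - s.mean) ** 2)) for s in (p1, p2, f1)
    )
    mse = ss_within / df_error
    coeffs = (-0.5, -0.5, 1.0)
    denom = sum(c * c / ni for c, ni in zip(coeffs, n))
    ss_contrast = d * d / denom
    if mse == 0:
        warnings.warn("zero within-class variance; p reported at the 0 boundary")
        f_ratio = math.inf if ss_contrast > 0 else 0.0
        p_value = 0.0 if ss_contrast > 0 else 1.0
    else:
        f_ratio = ss_contrast / mse
        p_value = float(stats.f.sf(f_ratio, 1, df_error))

    classification = classify_ratio(ratio, thresholds)
    if d == 0 or mean_p1 == mean_p2:
        toward = "neither"
    elif (d > 0) == (mean_p1 > mean_p2):
        toward = "P1"
    else:
        toward = "P2"
    return GeneActionResult(
        mean_p1=mean_p1,
        mean_p2=mean_p2,
        mean_f1=mean_f1,
        d=d,
        a_abs=a_abs,
        ratio=ratio,
        f_ratio=f_ratio,
        p_value=p_value,
        df_error=df_error,
        classification=classification,
        toward=toward,
    )


def read_trait_table(path: str | Path) -> dict[str, dict[str, TraitSample]]:
    """Read a long-format TSV (trait, genotype_class, value) into samples."""
    groups: dict[str, dict[str, list[float]]] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        try:
            ti, gi, vi = (header.index(c) for c in ("trait", "genotype_class", "value"))
        except ValueError:
            raise ValidationError(
                f"{path}: header must contain trait, genotype_class, value"
            ) from None
        for line_no, line in enumerate(handle, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(ti, gi, vi):
                raise ValidationError(f"{path}: row {line_no}: too few columns")
            try:
                value = float(parts[vi])
            except ValueError:
                raise ValidationError(
                    f"{path}: row {line_no}: not a number: {parts[vi]!r}"
                ) from None
            groups.setdefault(parts[ti], {}).setdefault(parts[gi], []).append(value)
    out: dict[str, dict[str, TraitSample]] = {}
    for trait, classes in groups.items():
        out[trait] = {
            cls: TraitSample(cls, tuple(values)) for cls, values in classes.items()
        }
    return out


def write_results(results: dict[str, GeneActionResult], path: str | Path) -> None:
    """One row per trait: means, d, |a|, d/|a|, F, p, classification."""
    with open(path, "w") as out:
        out.write(
            "trait\tmean_P1\tmean_P2\tmean_F1\td\ta_abs\tratio\tF\tp\tdf_error"
            "\tclassification\ttoward\n"
        )
        for trait, r in sorted(results.items()):
            out.write(
                f"{trait}\t{r.mean_p1:.6g}\t{r.mean_p2:.6g}\t{r.mean_f1:.6g}"
                f"\t{r.d:.6g}\t{r.a_abs:.6g}\t{r.ratio:.6g}\t{r.f_ratio:.6g}"
                f"\t{r.p_value:.6g}\t{r.df_error}\t{r.classification}\t{r.toward}\n"
            )
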