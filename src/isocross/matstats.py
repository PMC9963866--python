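"""Matrix correlation (Pearson, Mantel) and clustered-heatmap computation."""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import AnalysisError, ValidationError
from .popgen import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    tail: str  # greater | less | two_sided
    seed: int | None = None
    n: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


@dataclass
class ClusteredHeatmap:
    """Numeric contract of a clustered heatmap: unit-variance scaled
    columns, correlation-distance average-linkage merge trees and the
    dendrogram leaf orders."""

    row_labels: list[str]
    col_labels: list[str]
    scaled: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        with open(tsv_path, "w") as out:
            out.write("row\t" + "\t".join(self.col_labels) + "\n")
            for i, label in enumerate(self.row_labels):
                out.write(label + "\t" + "\t".join(f"{v:.6g}" for v in self.scaled[i]) + "\n")
        if json_path is not None:
            payload = {
                "row_order": self.row_order,
                "col_order": self.col_order,
                "row_linkage": self.row_linkage.tolist(),
                "col_linkage": self.col_linkage.tolist(),
            }
            Path(json_path).write_text(json.dumps(payload, indent=2))


def pearson_vector(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-distribution p.

    Raises on unequal/short inputs or zero variance (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def _lower_triangle(values: np.ndarray) -> np.ndarray:
    il = np.tril_indices(values.shape[0], k=-1)
    return values[il]


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 9999,
    tail: str = "greater",
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    Labels are reconciled by name. The observed r is the Pearson
    correlation of the lower-triangle vectors; one matrix's labels are
    permuted jointly on rows and columns. With random permutations
    p = (#permutations meeting the tail criterion + 1) / (n_perm + 1);
    with ``exact=True`` all n! relabelings are enumerated (identity
    included) and p is the exact fraction.
    """
    if tail not in ("greater", "less", "two_sided"):
        raise ValidationError(f"unknown tail: {tail!r}")
    if set(dm1.labels) != set(dm2.labels):
        only1 = sorted(set(dm1.labels) - set(dm2.labels))
        only2 = sorted(set(dm2.labels) - set(dm1.labels))
        raise ValidationError(
            f"label mismatch: only in first {only1}, only in second {only2}"
        )
    dm2 = dm2.reorder(dm1.labels)
    n = len(dm1.labels)
    if n < 3:
        raise AnalysisError("need at least 3 labels")
    a = _lower_triangle(dm1.values)
    b_mat = dm2.values

    def corr_with(perm: np.ndarray) -> float:
        b = _lower_triangle(b_mat[np.ix_(perm, perm)])
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr_with(np.arange(n))
    if math.isnan(r_obs):
        raise AnalysisError("zero variance in a distance vector")
    eps = 1e-12

    def meets(r_perm: float) -> bool:
        if tail == "greater":
            return r_perm >= r_obs - eps
        if tail == "less":
            return r_perm <= r_obs + eps
        return abs(r_perm) >= abs(r_obs) - eps

    if exact:
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
        count = sum(meets(corr_with(p)) for p in perms)
        return MantelResult(
            r=r_obs, p_value=count / len(perms), n_permutations=len(perms),
            tail=tail, seed=None, n=n,
        )
    if seed is None:
        raise ValidationError("a seed is required for random permutations")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if meets(corr_with(rng.permutation(n))):
            count += 1
    return MantelResult(
        r=r_obs, p_value=(count + 1) / (n_perm + 1), n_permutations=n_perm,
        tail=tail, seed=seed, n=n,
    )


def complete_submatrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Largest label subset without missing off-diagonal entries.

    Greedy: repeatedly drop the label with the most missing entries.
    """
    labels = list(dm.labels)
    values = dm.values.copy()
    while True:
        off = values.copy()
        np.fill_diagonal(off, 0.0)
        missing = np.isnan(off).sum(axis=1)
        if missing.max(initial=0) == 0:
            break
        drop = int(np.argmax(missing))
        labels.pop(drop)
        values = np.delete(np.delete(values, drop, axis=0), drop, axis=1)
    if len(labels) < 3:
        raise AnalysisError("fewer than 3 labels with complete distances")
    return DistanceMatrix(labels, values)


def _pairwise_correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances between rows, pairwise-complete."""
    n = matrix.shape[0]
    # with missing data, fewer than 3 shared entries makes the pairwise
    # correlation meaningless; complete 2-column profiles stay allowed
    min_shared = 3 if np.isnan(matrix).any() else 2
    out = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(matrix[i]) & ~np.isnan(matrix[j])
            if shared.sum() < min_shared:
                raise AnalysisError(
                    f"rows {i} and {j} share fewer than {min_shared} complete entries"
                )
            x, y = matrix[i][shared], matrix[j][shared]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise AnalysisError("constant profile: correlation distance undefined")
            out[k] = 1.0 - float(np.corrcoef(x, y)[0, 1])
            k += 1
    return np.clip(out, 0.0, None)


def cluster_heatmap(
    values: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> ClusteredHeatmap:
    """Unit-variance column scaling plus average-linkage clustering of
    rows and columns on correlation distance (1 - Pearson).

    Constant columns are excluded with a warning (their scaling is
    undefined). Missing values use pairwise-complete correlations.
    """
    values = np.asarray(values, dtype=float)
    row_labels = list(row_labels)
    col_labels = list(col_labels)
    if values.shape != (len(row_labels), len(col_labels)):
        raise ValidationError("values shape does not match labels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(values, axis=0, ddof=1)
    constant = (sd == 0) | np.isnan(sd)
    if constant.any():
        dropped = [c for c, flag in zip(col_labels, constant) if flag]
        warnings.warn(f"constant columns excluded from scaling: {dropped}")
        values = values[:, ~constant]
        col_labels = [c for c, flag in zip(col_labels, constant) if not flag]
        sd = sd[~constant]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise AnalysisError("need >= 2 rows and >= 2 non-constant columns")
    scaled = (values - np.nanmean(values, axis=0)) / sd
    if np.isnan(scaled).any():
        warnings.warn("missing values present; using pairwise-complete correlations")
    row_link = linkage(_pairwise_correlation_distance(scaled), method="average")
    col_link = linkage(_pairwise_correlation_distance(scaled.T), method="average")
    row_order = [row_labels[i] for i in leaves_list(row_link)]
    col_order = [col_labels[i] for i in leaves_list(col_link)]
    return ClusteredHeatmap(
        row_labels=row_labels,
        col_labels=col_labels,
        scaled=scaled,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
    )


def plot_heatmap(result: ClusteredHeatmap, path: str | Path) -> None:
    """Convenience image export of the clustered, scaled matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ri = [result.row_labels.index(r) for r in result.row_order]
    ci = [result.col_labels.index(c) for c in result.col_order]
    data = result.scaled[np.ix_(ri, ci)]
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(ci), 1 + 0.4 * len(ri)))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(ci)), result.col_order, rotation=90)
    ax.set_yticks(range(len(ri)), result.row_order)
    fig.colorbar(im, ax=ax, label="column z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
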