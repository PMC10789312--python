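"""Association-boosted distance metrics for microbiome samples.

Four pairwise distances are supported — weighted UniFrac, unweighted
UniFrac, Bray–Curtis and Hamming — each in a *boosted* form in which every
feature (tree branch or OTU) carries a nonnegative weight ``a_r`` derived
from the strength of its marginal association with the case–control label:

    a_r  ∝  -log10(p_r),    normalized to mean 1,

where ``p_r`` comes from a Welch two-sample t-test on abundances
(abundance-based metrics) or a chi-square / Fisher exact test on
presence/absence (presence-based metrics).  Setting all weights to 1
recovers the textbook metrics exactly.

The tree metrics operate on branch profiles (cumulative descendant
abundance per branch), with branch lengths ``b_r`` folded into the
weights; the non-tree metrics operate directly on the OTU table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .data_io import BranchProfiles

__all__ = [
    "BoostWeights",
    "DistanceMatrix",
    "abundance_pvalues",
    "presence_pvalues",
    "pvalues_to_weights",
    "weighted_unifrac",
    "unweighted_unifrac",
    "bray_curtis",
    "hamming",
]

P_FLOOR = 1e-300


@dataclass
class BoostWeights:
    """Nonnegative per-feature boosting weights, mean 1 by convention."""

    weights: pd.Series
    normalization: str = "mean1"

    def __post_init__(self) -> None:
        w = self.weights
        if (w < 0).any():
            raise ValueError("boost weights must be nonnegative")
        if not (w > 0).any():
            raise ValueError("boost weights must not be all zero")


@dataclass
class DistanceMatrix:
    """Pairwise distances; square (symmetric, zero diagonal) or test x train."""

    values: np.ndarray
    ids: list
    metric: str
    boosted: bool = False
    col_ids: list | None = None  # set for rectangular (cross) matrices

    def __post_init__(self) -> None:
        v = self.values
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        if self.col_ids is None:
            if v.shape[0] != v.shape[1]:
                raise ValueError("square matrix expected when col_ids is None")
            if not np.allclose(v, v.T, atol=1e-12):
                raise ValueError("distance matrix must be symmetric")

    @property
    def is_square(self) -> bool:
        return self.col_ids is None

    def to_frame(self) -> pd.DataFrame:
        cols = self.ids if self.col_ids is None else self.col_ids
        return pd.DataFrame(self.values, index=self.ids, columns=cols)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index), metric)


# ---------------------------------------------------------------------------
# association p-values and boosting weights
# ---------------------------------------------------------------------------

def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def abundance_pvalues(features, labels) -> pd.Series:
    """Welch two-sample t-test p-value per feature (cases vs controls).

    Features with zero within-group variance in both groups get p = 1.
    """
    X = pd.DataFrame(features)
    y = _check_labels(labels)
    a = X.values[y == 1]
    b = X.values[y == 0]
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.Series(p, index=X.columns)


def presence_pvalues(features, labels) -> pd.Series:
    """Presence/absence association p-value per feature.

    Builds the 2x2 presence (value > 0) x label table; uses Fisher's exact
    test when any expected cell count is below 5 or any observed cell is
    empty (the chi-square approximation is poorest exactly there), else
    Pearson chi-square without continuity correction.  Constant-presence
    features get p = 1.
    """
    X = pd.DataFrame(features)
    y = _check_labels(labels)
    present = (X.values > 0).astype(np.int64)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    n = n1 + n0
    a = present[y == 1].sum(axis=0)            # case, present
    c = present[y == 0].sum(axis=0)            # control, present
    b, d = n1 - a, n0 - c                      # absent cells
    col1, col0 = a + c, b + d
    out = np.ones(X.shape[1])
    variable = (col1 > 0) & (col0 > 0)
    # Pearson chi-square (no continuity correction), vectorized
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = n * (a * d - b * c) ** 2 / (n1 * n0 * col1 * col0)
    expected_min = np.minimum.reduce(
        [n1 * col1, n1 * col0, n0 * col1, n0 * col0]
    ) / n
    chi_ok = (
        variable & (expected_min >= 5)
        & (a > 0) & (b > 0) & (c > 0) & (d > 0)
    )
    out[chi_ok] = stats.chi2.sf(stat[chi_ok], df=1)
    for j in np.flatnonzero(variable & ~chi_ok):
        table = np.array([[a[j], b[j]], [c[j], d[j]]])
        out[j] = stats.fisher_exact(table, alternative="two-sided")[1]
    return pd.Series(out, index=X.columns)


def pvalues_to_weights(pvalues) -> BoostWeights:
    """Convert p-values to boosting weights a_r = normalized -log10(p).

    p is floored at 1e-300; raw weights are normalized to mean 1.  If all
    p-values equal 1 (no signal anywhere) the weights fall back to uniform.
    """
    p = pd.Series(pvalues, dtype=float)
    if (p < 0).any() or (p > 1).any() or p.isna().any():
        bad = p[(p < 0) | (p > 1) | p.isna()]
        raise ValueError(f"p-values outside (0, 1]: {bad.head().to_dict()}")
    raw = -np.log10(np.clip(p.values, P_FLOOR, 1.0))
    if raw.sum() == 0:
        warnings.warn("all p-values are 1; falling back to uniform weights")
        return BoostWeights(pd.Series(1.0, index=p.index), "uniform-fallback")
    w = raw / raw.mean()
    return BoostWeights(pd.Series(w, index=p.index), "mean1")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _feature_weights(
    weights: BoostWeights | None, columns: pd.Index, metric: str
) -> np.ndarray:
    if weights is None:
        return np.ones(len(columns))
    w = weights.weights
    if len(w) != len(columns) or not w.index.equals(pd.Index(columns)):
        if set(w.index) == set(columns):
            w = w.reindex(columns)
        else:
            raise ValueError(
                f"{metric}: boost-weight feature ids do not match the data"
            )
    return w.to_numpy(dtype=float)


def _ratio_distance(
    A: np.ndarray,
    B: np.ndarray | None,
    c: np.ndarray,
    presence: bool,
) -> np.ndarray:
    """Shared core of the two UniFrac forms.

    numerator(i,j)   = sum_r c_r |x_ir - x_jr|
    denominator(i,j) = sum_r c_r (p_ir + p_jr)            (weighted)
                     = sum_r c_r I(p_ir + p_jr > 0)       (unweighted)
    Pairs with zero denominator (both samples empty) get distance 0.
    """
    X = (A > 0).astype(float) if presence else A
    Y = X if B is None else ((B > 0).astype(float) if presence else B)
    num = cdist(X, Y, metric="cityblock", w=c) if c.size else np.zeros(
        (X.shape[0], Y.shape[0])
    )
    if presence:
        s_row = X @ c
        s_col = Y @ c
        shared = (X * c) @ Y.T
        den = s_row[:, None] + s_col[None, :] - shared
    else:
        s_row = X @ c
        s_col = Y @ c
        den = s_row[:, None] + s_col[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return D


def _bp_arrays(bp: BranchProfiles, other: BranchProfiles | None):
    A = bp.values.to_numpy(dtype=float)
    if other is None:
        B = None
    else:
        if not other.values.columns.equals(bp.values.columns):
            raise ValueError("branch ids of the two profile sets differ")
        B = other.values.to_numpy(dtype=float)
    return A, B


def weighted_unifrac(
    bp: BranchProfiles,
    weights: BoostWeights | None = None,
    other: BranchProfiles | None = None,
) -> DistanceMatrix:
    """(Boosted) weighted UniFrac distance.

    d(i,j) = sum_r b_r a_r |p_ir - p_jr| / sum_r b_r a_r (p_ir + p_jr).
    With unit weights this is the normalized weighted UniFrac distance.
    When *other* is given, rows of the result are samples of *bp* and
    columns are samples of *other* (a rectangular cross matrix).
    """
    a = _feature_weights(weights, bp.values.columns, "weighted_unifrac")
    c = bp.branch_lengths.to_numpy(dtype=float) * a
    A, B = _bp_arrays(bp, other)
    D = _ratio_distance(A, B, c, presence=False)
    return DistanceMatrix(
        values=D if other is not None else (D + D.T) / 2.0,
        ids=list(bp.values.index),
        metric="weighted_unifrac",
        boosted=weights is not None,
        col_ids=None if other is None else list(other.values.index),
    )


def unweighted_unifrac(
    bp: BranchProfiles,
    weights: BoostWeights | None = None,
    other: BranchProfiles | None = None,
) -> DistanceMatrix:
    """(Boosted) unweighted UniFrac distance on branch presence indicators.

    d(i,j) = sum_r b_r a_r |I(p_ir>0) - I(p_jr>0)|
             / sum_r b_r a_r I(p_ir + p_jr > 0).
    """
    a = _feature_weights(weights, bp.values.columns, "unweighted_unifrac")
    c = bp.branch_lengths.to_numpy(dtype=float) * a
    A, B = _bp_arrays(bp, other)
    D = _ratio_distance(A, B, c, presence=True)
    return DistanceMatrix(
        values=D if other is not None else (D + D.T) / 2.0,
        ids=list(bp.values.index),
        metric="unweighted_unifrac",
        boosted=weights is not None,
        col_ids=None if other is None else list(other.values.index),
    )


def _rel_arrays(rel: pd.DataFrame, other: pd.DataFrame | None):
    A = rel.to_numpy(dtype=float)
    if other is None:
        B = None
    else:
        if not other.columns.equals(rel.columns):
            raise ValueError("OTU ids of the two tables differ")
        B = other.to_numpy(dtype=float)
    return A, B


def bray_curtis(
    rel: pd.DataFrame,
    weights: BoostWeights | None = None,
    other: pd.DataFrame | None = None,
) -> DistanceMatrix:
    """(Boosted) Bray–Curtis distance: d(i,j) = sum_r a_r |p_ir - p_jr| / 2.

    On rows summing to 1 the unit-weight form equals classical Bray–Curtis,
    whose denominator sum_r (p_ir + p_jr) is the constant 2.
    """
    a = _feature_weights(weights, rel.columns, "bray_curtis")
    A, B = _rel_arrays(rel, other)
    D = cdist(A, A if B is None else B, metric="cityblock", w=a) / 2.0
    return DistanceMatrix(
        values=D if other is not None else (D + D.T) / 2.0,
        ids=list(rel.index),
        metric="bray_curtis",
        boosted=weights is not None,
        col_ids=None if other is None else list(other.index),
    )


def hamming(
    rel: pd.DataFrame,
    weights: BoostWeights | None = None,
    other: pd.DataFrame | None = None,
) -> DistanceMatrix:
    """(Boosted) Hamming distance on OTU presence indicators.

    d(i,j) = sum_r a_r |I(p_ir>0) - I(p_jr>0)|; with unit weights this is
    the number of OTUs whose presence status differs.
    """
    a = _feature_weights(weights, rel.columns, "hamming")
    A, B = _rel_arrays(rel, other)
    X = (A > 0).astype(float)
    Y = X if B is None else (B > 0).astype(float)
    D = cdist(X, Y, metric="cityblock", w=a)
    return DistanceMatrix(
        values=D if other is not None else (D + D.T) / 2.0,
        ids=list(rel.index),
        metric="hamming",
        boosted=weights is not None,
        col_ids=None if other is None else list(other.index),
    )
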