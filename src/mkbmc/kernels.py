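"""Gaussian similarity kernels from distance matrices.

K(i,j) = exp(-d(i,j)^2 / (2 sigma^2)), with the bandwidth sigma set to the
mean pairwise distance among training samples (strict upper triangle, so
self-distances do not bias it downward).  The same sigma is reused for
test-vs-train cross kernels — nothing at prediction time is derived from
test samples.  Kernels are treated purely as similarities; positive
semidefiniteness is neither assumed nor required downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosted_distances import DistanceMatrix

__all__ = ["KernelMatrix", "gaussian_kernel", "cross_kernel", "covariate_kernel"]


@dataclass
class KernelMatrix:
    """Similarity kernel; square train x train or rectangular test x train."""

    values: np.ndarray
    row_ids: list
    col_ids: list
    sigma: float
    metric: str

    def __post_init__(self) -> None:
        if self.sigma is None or not self.sigma > 0:
            raise ValueError("kernel bandwidth sigma must be positive")
        v = self.values
        if (v <= 0).any() or (v > 1 + 1e-12).any():
            raise ValueError("kernel entries must lie in (0, 1]")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")


def mean_upper_triangle(D: np.ndarray) -> float:
    """Mean of the strict upper triangle of a square matrix."""
    iu = np.triu_indices(D.shape[0], k=1)
    return float(D[iu].mean())


def gaussian_kernel(D: DistanceMatrix, sigma: float | None = None) -> KernelMatrix:
    """Transform a square distance matrix into a Gaussian kernel.

    When *sigma* is omitted it is set to the mean pairwise training
    distance.  A zero sigma (all training distances zero) is an error:
    the input is degenerate (all samples identical under the metric).
    """
    if not D.is_square:
        raise ValueError("gaussian_kernel needs a square training matrix; "
                         "use cross_kernel for test x train")
    if sigma is None:
        sigma = mean_upper_triangle(D.values)
    if not sigma > 0:
        raise ValueError(
            f"sigma computed as {sigma} for metric {D.metric!r}: all pairwise "
            "distances are zero (degenerate input)"
        )
    K = np.exp(-(D.values**2) / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, list(D.ids), list(D.ids), float(sigma), D.metric)


def cross_kernel(D_test_train: DistanceMatrix, sigma: float) -> KernelMatrix:
    """Gaussian kernel of test rows against training columns.

    *sigma* must be the bandwidth stored on the corresponding training
    kernel; it is never recomputed from test data.
    """
    if sigma is None or not sigma > 0:
        raise ValueError("cross_kernel requires the training sigma")
    K = np.exp(-(D_test_train.values**2) / (2.0 * sigma**2))
    cols = D_test_train.col_ids if D_test_train.col_ids is not None else D_test_train.ids
    return KernelMatrix(
        K, list(D_test_train.ids), list(cols), float(sigma), D_test_train.metric
    )


@dataclass
class CovariateScaler:
    """Training-set statistics needed to kernelize a covariate on new samples."""

    name: str
    mean: float
    sd: float
    sigma: float

    def transform(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


def covariate_kernel(
    x, name: str = "covariate", standardize: bool = True
) -> tuple[KernelMatrix, CovariateScaler]:
    """Gaussian kernel for one numeric covariate.

    The covariate is z-scored with training mean/sd, pairwise |x_i - x_j|
    is the distance, and sigma is its mean over training pairs.  The
    z-scoring makes the kernel invariant to affine rescaling of the raw
    covariate, so age-in-years and age-in-decades give identical kernels.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError(f"covariate {name!r} has non-finite values")
    mean = float(x.mean())
    sd = float(x.std(ddof=0)) if standardize else 1.0
    if standardize and sd == 0:
        raise ValueError(f"covariate {name!r} has zero variance")
    if not standardize:
        mean = 0.0
    z = (x - mean) / sd
    D = np.abs(z[:, None] - z[None, :])
    sigma = mean_upper_triangle(D)
    if not sigma > 0:
        raise ValueError(f"covariate {name!r} is constant after standardization")
    K = np.exp(-(D**2) / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    ids = list(range(len(x)))
    return (
        KernelMatrix(K, ids, ids, sigma, f"covariate:{name}"),
        CovariateScaler(name, mean, sd, sigma),
    )


def covariate_cross_kernel(
    x_test, x_train, scaler: CovariateScaler
) -> KernelMatrix:
    """Test-vs-train covariate kernel using frozen training statistics."""
    zt = scaler.transform(x_test)
    zr = scaler.transform(x_train)
    D = np.abs(zt[:, None] - zr[None, :])
    K = np.exp(-(D**2) / (2.0 * scaler.sigma**2))
    return KernelMatrix(
        K,
        list(range(len(zt))),
        list(range(len(zr))),
        scaler.sigma,
        f"covariate:{scaler.name}",
    )
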