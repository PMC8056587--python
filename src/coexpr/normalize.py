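"""Count normalization and variance stabilization.

Raw RNA-seq counts carry two nuisance structures that corrupt co-expression
estimates: per-sample library-size differences, and the negative-binomial
mean-variance relationship (highly expressed genes have larger variance, so
naive correlations reflect abundance rather than co-regulation).  This module
removes both in one pass:

1. **Size factors** by the median-of-ratios method: each sample's factor is
   the median, over reference genes, of its counts divided by the per-gene
   geometric mean across samples.  Genes with any zero count are dropped from
   the reference (their geometric mean is zero).
2. **Dispersion trend**: per-gene method-of-moments dispersions
   ``alpha_i = max(0, (s_i^2 - mu_i) / mu_i^2)`` on size-factor-normalized
   counts, followed by a robust (gamma-weighted iteratively reweighted least
   squares) fit of the parametric trend ``alpha(mu) = a0 + a1/mu``, where
   ``a0`` is the asymptotic dispersion and ``a1`` the extra-Poisson numerator.
3. **VST**: the closed-form antiderivative of ``1/sqrt(v(mu))`` for the
   trend's variance function ``v(mu) = mu*(1 + a1) + a0*mu^2``, affinely
   rescaled so the transform matches ``log2(q)`` for large normalized counts:

   ``vst(q) = log2( (2*a0*q + 1 + a1 + 2*sqrt(a0*q*(a0*q + 1 + a1))) / (4*a0) )``

   which is strictly increasing, finite at q = 0, and asymptotically
   homoscedastic with per-gene SD ~ sqrt(a0)/ln 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import NormalizationError, ParameterError

#: dispersion estimates outside these bounds are treated as outliers and
#: excluded from the trend fit
DISPERSION_OUTLIER_BOUNDS = (1e-4, 10.0)
#: minimum number of genes with normalized mean > MIN_TREND_MEAN required to fit
MIN_TREND_GENES = 10
MIN_TREND_MEAN = 0.5
#: floor for a0 in the closed-form transform (the log2 rescaling is undefined at 0)
A0_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ParameterError("counts must be a 2-D gene x sample matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.isfinite(self.values)) or np.any(
                self.values != np.floor(self.values)
            ):
                raise ParameterError("counts must be non-negative integers")
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            raise ParameterError("counts must be non-negative integers")
        self.gene_ids = np.asarray([str(g).upper() for g in self.gene_ids])
        self.sample_ids = np.asarray([str(s) for s in self.sample_ids])
        if len(self.gene_ids) != self.values.shape[0]:
            raise ParameterError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ParameterError("sample_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ParameterError("gene_ids must be unique after uppercasing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParameterError("sample_ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="gene"
        )

    @classmethod
    def from_hdf5(cls, path) -> "CountMatrix":
        """Read datasets /counts (genes x samples), /genes, /samples."""
        import h5py

        with h5py.File(path, "r") as fh:
            counts = fh["counts"][...]
            genes = [g.decode() if isinstance(g, bytes) else str(g) for g in fh["genes"][...]]
            samples = [
                s.decode() if isinstance(s, bytes) else str(s) for s in fh["samples"][...]
            ]
        return cls(counts, np.asarray(genes), np.asarray(samples))


@dataclass
class DispersionTrend:
    """Fitted parametric mean-dispersion trend alpha(mu) = a0 + a1/mu."""

    a0: float
    a1: float
    n_genes_used: int = 0
    converged: bool = True

    def alpha(self, mu):
        return self.a0 + self.a1 / np.asarray(mu, dtype=float)


@dataclass
class VstMatrix:
    """Variance-stabilized gene x sample matrix (log2-like scale)."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    size_factors: np.ndarray
    trend: DispersionTrend

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="gene", float_format="%.8g"
        )

    def sidecar(self) -> dict:
        return {
            "size_factors": dict(zip(map(str, self.sample_ids), map(float, self.size_factors))),
            "trend_params": {"a0": self.trend.a0, "a1": self.trend.a1},
            "n_genes_used": self.trend.n_genes_used,
            "converged": self.trend.converged,
            "dispersion_outlier_bounds": list(DISPERSION_OUTLIER_BOUNDS),
        }

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=1, sort_keys=True)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors against the per-gene geometric mean.

    Only genes with all-positive counts form the reference; with none usable
    a NormalizationError is raised.
    """
    vals = counts.values
    usable = np.all(vals > 0, axis=1)
    if not usable.any():
        raise NormalizationError(
            "cannot compute size factors: no gene has all-positive counts "
            "to form the geometric-mean reference"
        )
    logs = np.log(vals[usable].astype(float))
    log_geomean = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geomean, axis=0))
    return sf


def fit_dispersion_trend(counts: CountMatrix, sf: np.ndarray) -> DispersionTrend:
    """Fit alpha(mu) = a0 + a1/mu to per-gene method-of-moments dispersions.

    Uses gamma-family IRLS (weights 1/fitted^2) with non-negativity enforced
    at every step; on fit failure falls back to a0 = median positive
    dispersion, a1 = 0, with a warning.
    """
    q = counts.values / np.asarray(sf, dtype=float)[None, :]
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu) / mu**2
    expressed = mu > MIN_TREND_MEAN
    if expressed.sum() < MIN_TREND_GENES:
        raise NormalizationError(
            f"dispersion trend requires >= {MIN_TREND_GENES} genes with "
            f"normalized mean > {MIN_TREND_MEAN}; got {int(expressed.sum())}"
        )
    alpha = np.where(np.isfinite(alpha), alpha, -1.0)
    positive = expressed & (alpha > 0)
    if not positive.any():
        raise NormalizationError(
            "dispersion trend fit failed: no gene has positive extra-Poisson dispersion"
        )
    lo, hi = DISPERSION_OUTLIER_BOUNDS
    keep = positive & (alpha >= lo) & (alpha <= hi)
    if keep.sum() < MIN_TREND_GENES:
        keep = positive

    y = alpha[keep]
    x = 1.0 / mu[keep]
    X = np.column_stack([np.ones_like(x), x])
    try:
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        coef = np.clip(coef, 0.0, None)
        for _ in range(50):
            fitted = np.clip(X @ coef, 1e-10, None)
            sqw = 1.0 / fitted
            new, _ = nnls(X * sqw[:, None], y * sqw)
            if np.allclose(new, coef, rtol=1e-6, atol=1e-12):
                coef = new
                break
            coef = new
        a0, a1 = float(coef[0]), float(coef[1])
        if not (np.isfinite(a0) and np.isfinite(a1)):
            raise FloatingPointError("non-finite trend coefficients")
        converged = True
    except Exception:  # noqa: BLE001 - any numerical failure triggers the fallback
        warnings.warn(
            "dispersion trend fit diverged; falling back to median dispersion",
            RuntimeWarning,
            stacklevel=2,
        )
        a0, a1, converged = float(np.median(alpha[positive])), 0.0, False
    return DispersionTrend(a0=a0, a1=a1, n_genes_used=int(keep.sum()), converged=converged)


def vst_values(q, a0: float, a1: float) -> np.ndarray:
    """Closed-form variance-stabilizing map applied to normalized counts q.

    Antiderivative of 1/sqrt(v(mu)) for v(mu) = mu*(1+a1) + a0*mu^2, rescaled
    by sqrt(a0)/ln 2 and shifted so vst(q) -> log2(q) as q -> infinity.
    """
    q = np.asarray(q, dtype=float)
    a0 = max(float(a0), A0_FLOOR)
    b = 1.0 + float(a1)
    return np.log2((2.0 * a0 * q + b + 2.0 * np.sqrt(a0 * q * (a0 * q + b))) / (4.0 * a0))


def vst(counts: CountMatrix) -> VstMatrix:
    """Size-factor normalization, trend fit, and closed-form transform in one pass."""
    sf = size_factors(counts)
    trend = fit_dispersion_trend(counts, sf)
    q = counts.values / sf[None, :]
    values = vst_values(q, trend.a0, trend.a1)
    return VstMatrix(
        values=values,
        gene_ids=counts.gene_ids.copy(),
        sample_ids=counts.sample_ids.copy(),
        size_factors=sf,
        trend=trend,
    )
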