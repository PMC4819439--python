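"""Pairwise negative-binomial differential expression.

The model: counts ``K_gj ~ NB(mu_g * s_j, phi_g)`` with variance
``mu + phi * mu**2``.  Normalization uses the median-of-ratios size factor;
per-gene dispersion is a pooled method-of-moments estimate floored at
``phi_min``.  Because replicate numbers are small (typically 3 vs 3), the
test moderates the gene-wise dispersion toward the across-gene median with
a prior weight of ``prior_df`` degrees of freedom and refers the Wald
statistic on the difference of log normalized means to a t distribution
with ``(n_A + n_B - 2) + prior_df`` degrees of freedom — the usual
empirical-Bayes device for keeping small-n variance tests honest without
giving up power.  P-values are
Benjamini-Hochberg adjusted across the tested genes only; genes below the
``min_count`` mean in both conditions are excluded from testing and from
the BH family.

The user-facing surface is ``PairwiseNB(matrix, cond_a, cond_b, time_h)``
whose :meth:`PairwiseNB.fit` returns a :class:`DETable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = ["size_factors", "normalized_counts", "estimate_dispersion",
           "bh_adjust", "PairwiseNB", "DETable", "test_pairwise"]

PSEUDOCOUNT = 0.5  # normalized-count pseudocount for finite log fold-changes
PHI_MIN = 0.01


class ContrastError(ValueError):
    """A requested condition/time cell is absent or degenerate."""


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame | ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    ``factor_j = median over genes g (all counts positive) of
    count_gj / geometric_mean_g(counts)``.

    Raises
    ------
    ContrastError
        If no gene has a positive count in every sample (the reference
        geometric mean would be undefined for all genes).
    """
    if isinstance(counts, ExpressionMatrix):
        counts = counts.counts
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ContrastError("no gene with positive counts in every sample")
    logs = np.log(values[all_positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    # median on the ratio scale (matters when the gene count is even)
    factors = np.median(np.exp(logs - log_geomean), axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame | ExpressionMatrix,
                      factors: pd.Series | None = None) -> pd.DataFrame:
    if isinstance(counts, ExpressionMatrix):
        counts = counts.counts
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _raw_dispersion(norm: pd.DataFrame,
                    groups: Sequence[Sequence[str]]) -> np.ndarray:
    """Pooled, unfloored method-of-moments dispersion (may be negative)."""
    num = np.zeros(len(norm))
    den = 0.0
    for cols in groups:
        if len(cols) < 2:
            continue
        sub = norm[list(cols)].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_c = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        num += (len(cols) - 1) * phi_c
        den += len(cols) - 1
    if den == 0:
        raise ContrastError("dispersion needs >= 2 replicates in at least one group")
    return num / den


def estimate_dispersion(norm: pd.DataFrame,
                        groups: Sequence[Sequence[str]],
                        phi_min: float = PHI_MIN) -> pd.Series:
    """Pooled method-of-moments NB dispersion per gene.

    For each replicate group with >= 2 samples the moment estimate is
    ``(s^2 - mu) / mu^2`` on normalized counts; group estimates are pooled
    with weights ``n_c - 1`` and floored at ``phi_min``.  Genes whose sample
    variance does not exceed the mean (Poisson-like or degenerate) get
    ``phi_min``.
    """
    phi = np.maximum(_raw_dispersion(norm, groups), phi_min)
    return pd.Series(phi, index=norm.index, name="dispersion")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# the pairwise model
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Results of one pairwise NB contrast.

    ``frame`` has one row per *tested* gene with columns
    ``base_mean, log2fc, p, padj, direction`` (``direction`` in
    {up, down, none}; ``up`` means higher in ``cond_b``).
    """

    cond_a: str
    cond_b: str
    time_h: float
    alpha: float
    lfc_min: float
    frame: pd.DataFrame
    n_excluded: int = 0

    def genes(self, direction: str) -> set[str]:
        """Gene ids called in one direction ('up' or 'down')."""
        return set(self.frame.index[self.frame["direction"] == direction])

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["direction"] != "none"]

    def summary(self) -> str:
        n = len(self.frame)
        up, down = len(self.genes("up")), len(self.genes("down"))
        lines = [
            f"Pairwise NB differential expression: {self.cond_b} vs {self.cond_a} "
            f"at {self.time_h:g} h",
            f"  genes tested          {n}",
            f"  genes excluded (low)  {self.n_excluded}",
            f"  up   (padj<{self.alpha:g}, log2fc>=+{self.lfc_min:g})  {up}",
            f"  down (padj<{self.alpha:g}, log2fc<=-{self.lfc_min:g})  {down}",
        ]
        return "\n".join(lines)

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, path: str | Path, cond_a: str = "?", cond_b: str = "?",
             time_h: float = float("nan"), alpha: float = 0.05,
             lfc_min: float = 1.0) -> "DETable":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(cond_a, cond_b, time_h, alpha, lfc_min, frame)


class PairwiseNB:
    """Two-group negative-binomial contrast between condition labels.

    Parameters
    ----------
    matrix
        Full experiment; the two conditions at ``time_h`` are selected here.
    cond_a, cond_b
        Condition labels; fold-changes are reported as B over A.
    time_h
        Time point shared by both groups.
    alpha, lfc_min
        Significance level on the BH-adjusted p-value and minimum absolute
        log2 fold-change for a directional call (``lfc_min`` may be 0).
    min_count
        A gene is tested only if its mean normalized count reaches this
        value in at least one condition.
    prior_df
        Weight (in degrees of freedom) of the across-gene median dispersion
        when moderating the gene-wise estimate; also added to the reference
        t distribution's degrees of freedom.
    """

    def __init__(self, matrix: ExpressionMatrix, cond_a: str, cond_b: str,
                 time_h: float, *, alpha: float = 0.05, lfc_min: float = 1.0,
                 min_count: float = 5.0, phi_min: float = PHI_MIN,
                 prior_df: float = 5.0):
        cols_a = matrix.samples_for(cond_a, time_h)
        cols_b = matrix.samples_for(cond_b, time_h)
        if not cols_a:
            raise ContrastError(f"no samples for condition {cond_a!r} at {time_h} h")
        if not cols_b:
            raise ContrastError(f"no samples for condition {cond_b!r} at {time_h} h")
        if len(cols_a) + len(cols_b) < 3 or max(len(cols_a), len(cols_b)) < 2:
            raise ContrastError(
                f"contrast {cond_b} vs {cond_a} at {time_h} h needs >= 2 "
                f"replicates in at least one condition "
                f"({len(cols_a)} vs {len(cols_b)} found)"
            )
        self.matrix = matrix
        self.cond_a, self.cond_b, self.time_h = cond_a, cond_b, time_h
        self.cols_a, self.cols_b = cols_a, cols_b
        self.alpha, self.lfc_min = alpha, lfc_min
        self.min_count, self.phi_min = min_count, phi_min
        self.prior_df = prior_df

    def fit(self) -> DETable:
        counts = self.matrix.counts[self.cols_a + self.cols_b]
        factors = size_factors(counts)
        norm = normalized_counts(counts, factors)
        phi_raw = _raw_dispersion(norm, [self.cols_a, self.cols_b])

        a = norm[self.cols_a].to_numpy(dtype=float)
        b = norm[self.cols_b].to_numpy(dtype=float)
        n_a, n_b = a.shape[1], b.shape[1]
        mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)

        tested = (mu_a >= self.min_count) | (mu_b >= self.min_count)
        n_excluded = int((~tested).sum())

        mu_a_t = mu_a[tested] + PSEUDOCOUNT
        mu_b_t = mu_b[tested] + PSEUDOCOUNT

        # moderate the gene-wise dispersion toward the across-gene median
        resid_df = n_a + n_b - 2
        phi_common = max(float(np.median(phi_raw[tested])), 0.0)
        phi_mod = (resid_df * phi_raw[tested] + self.prior_df * phi_common) / (
            resid_df + self.prior_df
        )
        phi_t = np.maximum(phi_mod, self.phi_min)

        log2fc = np.log2(mu_b_t / mu_a_t)
        # Var(log mean) by the delta method: (mu + phi mu^2) / (n mu^2)
        se2 = (1.0 / (n_a * mu_a_t) + phi_t / n_a
               + 1.0 / (n_b * mu_b_t) + phi_t / n_b)
        wald = np.log(mu_b_t / mu_a_t) / np.sqrt(se2)
        df = resid_df + self.prior_df
        p = 2.0 * stats.t.sf(np.abs(wald), df)
        padj = bh_adjust(p)

        direction = np.full(p.shape, "none", dtype=object)
        sig = padj < self.alpha
        direction[sig & (log2fc >= self.lfc_min)] = "up"
        direction[sig & (log2fc <= -self.lfc_min)] = "down"

        frame = pd.DataFrame(
            {
                "base_mean": (mu_a[tested] * n_a + mu_b[tested] * n_b) / (n_a + n_b),
                "log2fc": log2fc,
                "p": p,
                "padj": padj,
                "direction": direction,
            },
            index=counts.index[tested],
        )
        frame.index.name = "gene_id"
        return DETable(self.cond_a, self.cond_b, self.time_h, self.alpha,
                       self.lfc_min, frame, n_excluded)


def test_pairwise(matrix: ExpressionMatrix, cond_a: str, cond_b: str,
                  time_h: float, **kwargs) -> DETable:
    """Functional shorthand for ``PairwiseNB(...).fit()``."""
    return PairwiseNB(matrix, cond_a, cond_b, time_h, **kwargs).fit()
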