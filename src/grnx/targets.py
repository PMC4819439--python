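"""Direct-repression target calling and signature correlations.

A gene in a signature is a *direct* repression target of an induced TF if
it is both significantly downregulated on induction and carries an
associated binding event for that TF; downregulated-but-unbound genes are
*indirect* targets.  Thresholds are inherited: "repressed" comes from the
differential-expression module's settings, "bound" from the association
module's distance cap — there are no separate knobs here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DETable, normalized_counts
from .io_formats import ExpressionMatrix
from .signatures import GeneSignature

__all__ = [
    "DirectTargetCall",
    "call_direct_targets",
    "TargetCallSummary",
    "repression_strength_profile",
    "signature_correlation",
    "CorrelationReport",
]

CALL_ORDER = ("direct_repressed", "indirect_repressed",
              "bound_not_repressed", "unaffected")


@dataclass(frozen=True)
class DirectTargetCall:
    gene_id: str
    tf: str
    in_signature: bool
    repressed: bool
    bound: bool

    @property
    def call(self) -> str:
        if self.repressed and self.bound:
            return "direct_repressed"
        if self.repressed:
            return "indirect_repressed"
        if self.bound:
            return "bound_not_repressed"
        return "unaffected"


@dataclass(frozen=True)
class TargetCallSummary:
    tf: str
    signature: str
    n_signature: int
    n_repressed: int
    n_repressed_bound: int
    background_bound_fraction: float | None = None

    @property
    def fraction_repressed(self) -> float:
        return self.n_repressed / self.n_signature

    @property
    def fraction_repressed_bound(self) -> float:
        if self.n_repressed == 0:
            return float("nan")
        return self.n_repressed_bound / self.n_repressed

    def as_dict(self) -> dict:
        return {
            "tf": self.tf,
            "signature": self.signature,
            "n_signature": self.n_signature,
            "n_repressed": self.n_repressed,
            "n_repressed_bound": self.n_repressed_bound,
            "fraction_repressed": self.fraction_repressed,
            "fraction_repressed_bound": self.fraction_repressed_bound,
            "background_bound_fraction": self.background_bound_fraction,
        }


def call_direct_targets(signature: GeneSignature, repressed: set[str],
                        bound: set[str], tf: str = "TF",
                        background: set[str] | None = None,
                        ) -> tuple[list[DirectTargetCall], TargetCallSummary]:
    """Partition a signature into direct/indirect/bound-only/unaffected.

    Returns one call per signature gene (the four categories partition the
    signature) plus a summary with the fraction of the signature repressed,
    the fraction of repressed genes that are bound, and — when a background
    gene set is supplied — the matched background bound fraction.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    calls = [
        DirectTargetCall(g, tf, True, g in repressed, g in bound)
        for g in sorted(signature.gene_ids)
    ]
    n_rep = sum(c.repressed for c in calls)
    n_rep_bound = sum(c.repressed and c.bound for c in calls)
    bg_frac = None
    if background:
        bg_frac = len(set(background) & bound) / len(background)
    summary = TargetCallSummary(tf, signature.name, len(calls), n_rep,
                                n_rep_bound, bg_frac)
    return calls, summary


def calls_frame(calls: Sequence[DirectTargetCall]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "tf": [c.tf for c in calls],
            "repressed": [c.repressed for c in calls],
            "bound": [c.bound for c in calls],
            "call": [c.call for c in calls],
        }
    ).set_index("gene_id")
    return frame


def repression_strength_profile(de_table: DETable,
                                signatures: Sequence[GeneSignature],
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-repression distributions per signature, with rank-sum contrasts.

    For each signature, collects ``-log2fc`` over its *repressed* genes in
    the induction contrast; returns (per-signature medians and sizes, a
    frame of two-sided Mann-Whitney p-values between signature pairs).
    Signatures with no repressed genes get an NaN median and are skipped in
    the pairwise comparisons.
    """
    repressed = de_table.genes("down")
    dist: dict[str, np.ndarray] = {}
    rows = []
    for sig in signatures:
        genes = sorted(sig.gene_ids & repressed)
        values = -de_table.frame.loc[genes, "log2fc"].to_numpy()
        dist[sig.name] = values
        rows.append(
            {
                "signature": sig.name,
                "n_repressed": len(values),
                "median_fold_log2": float(np.median(values)) if len(values) else float("nan"),
            }
        )
    medians = pd.DataFrame(rows).set_index("signature")
    names = [s.name for s in signatures]
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(dist[a]) and len(dist[b]):
                p = stats.mannwhitneyu(dist[a], dist[b], alternative="two-sided").pvalue
                pmat.loc[a, b] = pmat.loc[b, a] = float(p)
    return medians, pmat


@dataclass(frozen=True)
class CorrelationReport:
    signature: str
    condition_a: str
    condition_b: str
    time_h: float
    r: float


def signature_correlation(matrix: ExpressionMatrix, signature: GeneSignature,
                          condition_pairs: Sequence[tuple[str, str]],
                          time_h: float) -> list[CorrelationReport]:
    """Pearson r between conditions on signature genes' log expression.

    Expression is the mean normalized count per condition at ``time_h``,
    log2-transformed with a 0.5 pseudocount, restricted to signature genes
    present in the matrix.
    """
    genes = sorted(g for g in signature.gene_ids if g in matrix.gene_ids)
    if len(genes) < 3:
        raise ValueError(
            f"signature {signature.name!r} has {len(genes)} genes in the matrix; "
            "need >= 3 for a correlation"
        )
    conditions = sorted({c for pair in condition_pairs for c in pair})
    norm = normalized_counts(matrix.counts)  # shared factors across conditions
    profiles: dict[str, np.ndarray] = {}
    for cond in conditions:
        cols = matrix.samples_for(cond, time_h)
        if not cols:
            raise ValueError(f"no samples for condition {cond!r} at {time_h} h")
        means = norm.loc[genes, cols].mean(axis=1).to_numpy()
        profiles[cond] = np.log2(means + 0.5)
    reports = []
    for a, b in condition_pairs:
        r = float(stats.pearsonr(profiles[a], profiles[b])[0])
        reports.append(CorrelationReport(signature.name, a, b, time_h, r))
    return reports
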