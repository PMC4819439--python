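"""Domain gene signatures and temporal response classes.

A *signature* is a gene set defined as the intersection of directional
differential-expression calls across named contrasts (e.g. "dorsal" =
up in dorsal-vs-p3 at 36 h AND up in dorsal-vs-pMN at 36 h), optionally
further restricted to genes whose expression peaks at a stated time.  The
rule that produced a signature is stored with it, so membership is always
recomputable from the DE tables.

Temporal classes ("early", "intermediate", "late") record the first grid
time at which a gene's mean normalized expression exceeds a fold threshold
over its value at the first sampled time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .diffexpr import DETable, normalized_counts
from .io_formats import ExpressionMatrix

__all__ = [
    "ContrastCriterion",
    "FoldGapCriterion",
    "SignatureRule",
    "GeneSignature",
    "derive_signature",
    "classify_temporal",
    "repressed_by_induction",
    "fraction_of_signature",
    "load_rules",
]


@dataclass(frozen=True)
class ContrastCriterion:
    """One conjunct of a signature rule: a directional DE requirement."""

    contrast: str  # key into the DE-table mapping, e.g. "dorsal_vs_p3@36"
    direction: str  # 'up' or 'down' (direction of cond_b relative to cond_a)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")


@dataclass(frozen=True)
class FoldGapCriterion:
    """Encodes a "much greater" ordering between two contrasts.

    Keeps genes whose log2 fold-change in ``contrast_large`` exceeds that
    in ``contrast_small`` by at least ``min_gap`` (e.g. "higher in FP than
    p3, and *much* higher than in pMN": large = FP-vs-pMN, small =
    FP-vs-p3).  Genes absent from either table are dropped.
    """

    contrast_large: str
    contrast_small: str
    min_gap: float = 1.0


@dataclass(frozen=True)
class SignatureRule:
    name: str
    criteria: tuple[ContrastCriterion, ...]
    gaps: tuple[FoldGapCriterion, ...] = ()
    peak_time_h: float | None = None
    peak_time_condition: str | None = None

    def __post_init__(self) -> None:
        if self.peak_time_h is not None and self.peak_time_condition is None:
            raise ValueError("peak_time_h requires peak_time_condition")


@dataclass(frozen=True)
class GeneSignature:
    """Named gene set plus the machine-readable rule that produced it."""

    name: str
    gene_ids: frozenset[str]
    rule: SignatureRule

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


def derive_signature(de_tables: Mapping[str, DETable], rule: SignatureRule,
                     matrix: ExpressionMatrix | None = None) -> GeneSignature:
    """Intersect directional DE calls (and an optional peak-time filter).

    ``de_tables`` maps contrast names to fitted :class:`DETable` objects;
    every contrast named by the rule must be present.  When the rule has a
    ``peak_time_h``, ``matrix`` must be given: genes are kept only if their
    maximum mean normalized expression in ``peak_time_condition`` across the
    sampled time grid occurs at ``peak_time_h``.
    """
    members: set[str] | None = None
    for crit in rule.criteria:
        if crit.contrast not in de_tables:
            raise KeyError(
                f"rule {rule.name!r} references missing contrast {crit.contrast!r}"
            )
        genes = de_tables[crit.contrast].genes(crit.direction)
        members = genes if members is None else members & genes
    if members is None:
        members = set()
    for gap in rule.gaps:
        for key in (gap.contrast_large, gap.contrast_small):
            if key not in de_tables:
                raise KeyError(
                    f"rule {rule.name!r} references missing contrast {key!r}"
                )
        large = de_tables[gap.contrast_large].frame["log2fc"]
        small = de_tables[gap.contrast_small].frame["log2fc"]
        members = {
            g for g in members
            if g in large.index and g in small.index
            and large[g] >= small[g] + gap.min_gap
        }
    if rule.peak_time_h is not None:
        if matrix is None:
            raise ValueError("peak-time rules need the expression matrix")
        peak_at = _peak_times(matrix, rule.peak_time_condition)
        members = {g for g in members if peak_at.get(g) == rule.peak_time_h}
    if not members:
        warnings.warn(f"signature {rule.name!r} is empty", stacklevel=2)
    return GeneSignature(rule.name, frozenset(members), rule)


def _peak_times(matrix: ExpressionMatrix, condition: str) -> dict[str, float]:
    """Grid time of maximum mean normalized expression, per gene."""
    times = sorted({s.time_h for s in matrix.samples if s.condition == condition})
    if not times:
        raise ValueError(f"no samples for condition {condition!r}")
    cols = [n for t in times for n in matrix.samples_for(condition, t)]
    norm = normalized_counts(matrix.counts[cols])
    means = pd.DataFrame(
        {t: norm[matrix.samples_for(condition, t)].mean(axis=1) for t in times}
    )
    argmax = means.to_numpy().argmax(axis=1)  # first maximum wins ties
    return {g: times[i] for g, i in zip(means.index, argmax)}


def classify_temporal(matrix: ExpressionMatrix, condition: str,
                      grid: Sequence[float] | None = None,
                      fold_threshold: float = 3.0) -> pd.DataFrame:
    """Classify genes by induction time relative to the first grid point.

    The class is determined by the earliest grid time at which the mean
    normalized expression reaches ``fold_threshold`` times its value at the
    first grid point (a 0.5 pseudocount keeps zero baselines finite):
    the first post-baseline grid point is "early", the next "intermediate",
    anything later "late"; genes never reaching the threshold are
    "unclassified".  Returns a frame indexed by gene with a ``temporal_class``
    column; the classes partition the classified genes.
    """
    if grid is None:
        grid = sorted({s.time_h for s in matrix.samples if s.condition == condition})
    grid = list(grid)
    if len(grid) < 3:
        raise ValueError("temporal classification needs >= 3 time points")
    cols = [n for t in grid for n in matrix.samples_for(condition, t)]
    if not cols:
        raise ValueError(f"no samples for condition {condition!r} on the grid")
    norm = normalized_counts(matrix.counts[cols])
    means = np.column_stack(
        [norm[matrix.samples_for(condition, t)].mean(axis=1) for t in grid]
    )
    baseline = means[:, 0] + 0.5
    reached = means >= fold_threshold * baseline[:, None]
    reached[:, 0] = False  # the baseline point itself never classifies
    first = np.where(reached.any(axis=1), reached.argmax(axis=1), -1)
    labels = np.full(len(means), "unclassified", dtype=object)
    labels[first == 1] = "early"
    labels[first == 2] = "intermediate"
    labels[first >= 3] = "late"
    return pd.DataFrame({"temporal_class": labels}, index=norm.index)


def repressed_by_induction(de_table: DETable) -> set[str]:
    """Genes significantly down in the induced condition vs its base."""
    return de_table.genes("down")


def fraction_of_signature(signature: GeneSignature, gene_set: set[str]) -> float:
    """Fraction of signature members contained in ``gene_set`` (NaN if empty)."""
    if len(signature) == 0:
        return float("nan")
    return len(signature.gene_ids & gene_set) / len(signature)


# ---------------------------------------------------------------------------
# YAML rule files
# ---------------------------------------------------------------------------

def load_rules(path) -> list[SignatureRule]:
    """Load signature rules from YAML.

    Schema: a list of mappings with keys ``name``, ``contrasts`` (each with
    ``contrast`` and ``direction``), optional ``gaps`` (each with
    ``contrast_large``, ``contrast_small`` and optional ``min_gap``), and
    optional ``peak_time_h`` + ``peak_time_condition``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw:
        crits = tuple(
            ContrastCriterion(c["contrast"], c["direction"]) for c in entry["contrasts"]
        )
        gaps = tuple(
            FoldGapCriterion(g["contrast_large"], g["contrast_small"],
                             g.get("min_gap", 1.0))
            for g in entry.get("gaps", ())
        )
        rules.append(
            SignatureRule(
                name=entry["name"],
                criteria=crits,
                gaps=gaps,
                peak_time_h=entry.get("peak_time_h"),
                peak_time_condition=entry.get("peak_time_condition"),
            )
        )
    return rules
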