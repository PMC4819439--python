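"""Peak-to-gene association, binding enrichment, and CRE co-occupancy.

Peaks are linked to the gene whose TSS is nearest to the peak summit, with
a configurable distance cap (default 100 kb) and a promoter/distal split at
1 kb.  Enrichment of binding in a gene set against a background uses the
2x2 chi-squared statistic without continuity correction, with Fisher's
exact test reported alongside whenever any expected cell is below 5.

Cis-regulatory elements (CREs) are built by trimming every peak to a
summit-centered window (default +/-150 bp) and merging overlapping windows
across all TFs; co-occupancy statistics (which fraction of one TF's CREs
are shared with another, how many distinct CREs a gene has, how repressor
and activator binding overlap) are computed on the merged elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DETable
from .io_formats import GeneAnnotation, Peak

__all__ = [
    "PeakGeneLink",
    "EnrichmentResult",
    "CRE",
    "top_peaks",
    "associate_peaks",
    "bound_genes",
    "binding_enrichment",
    "non_changing_background",
    "merge_cres",
    "sharing_fraction",
    "cres_per_gene",
    "activator_repressor_overlap",
]

logger = logging.getLogger(__name__)

MAX_DISTANCE = 100_000
PROMOTER_HALFWIDTH = 1_000
CRE_HALFWIDTH = 150
TOP_N_PEAKS = 3_000


@dataclass(frozen=True)
class PeakGeneLink:
    """A peak assigned to its nearest-TSS gene.

    ``signed_distance`` is strand-oriented: positive means the summit lies
    downstream of the TSS (in the gene's reading direction).
    """

    peak: Peak
    gene_id: str
    signed_distance: int
    category: str  # 'promoter' or 'distal'


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 bound/unbound x in-set/background contingency outcome."""

    set_name: str
    tf: str
    k_set: int
    n_set: int
    k_bg: int
    n_bg: int
    chi2: float
    p: float
    fisher_p: float | None = None  # filled when any expected cell < 5

    @property
    def set_fraction(self) -> float:
        return self.k_set / self.n_set

    @property
    def bg_fraction(self) -> float:
        return self.k_bg / self.n_bg


@dataclass(frozen=True)
class CRE:
    """Merged summit-window interval with its TF occupants."""

    chrom: str
    start: int
    end: int
    occupants: frozenset[str]
    n_peaks: int
    gene_id: str | None = None  # filled by linking midpoints to genes

    @property
    def midpoint(self) -> int:
        return (self.start + self.end - 1) // 2


# ---------------------------------------------------------------------------
# peak filtering and association
# ---------------------------------------------------------------------------

def top_peaks(peaks: Sequence[Peak], n: int = TOP_N_PEAKS) -> list[Peak]:
    """Keep the n highest-scoring peaks (ties broken by position)."""
    ranked = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))
    kept = ranked[:n]
    kept.sort(key=lambda p: (p.chrom, p.start, p.end))
    return kept


def associate_peaks(peaks: Sequence[Peak], annotation: Sequence[GeneAnnotation],
                    max_distance: int = MAX_DISTANCE,
                    promoter_halfwidth: int = PROMOTER_HALFWIDTH) -> list[PeakGeneLink]:
    """Link each peak to the gene with the nearest TSS (by summit distance).

    Peaks whose nearest TSS is farther than ``max_distance``, or whose
    chromosome has no annotated gene, are dropped (and counted in the log).
    Equidistant TSSs are resolved toward the lexicographically smaller gene
    id, with a warning.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    by_chrom: dict[str, tuple[np.ndarray, list[GeneAnnotation]]] = {}
    for chrom in {g.chrom for g in annotation}:
        genes = sorted(
            (g for g in annotation if g.chrom == chrom),
            key=lambda g: (g.tss, g.gene_id),
        )
        by_chrom[chrom] = (np.array([g.tss for g in genes]), genes)

    links: list[PeakGeneLink] = []
    n_unlinked_chrom = n_unlinked_far = n_ties = 0
    for peak in peaks:
        if peak.chrom not in by_chrom:
            n_unlinked_chrom += 1
            continue
        tss_arr, genes = by_chrom[peak.chrom]
        idx = int(np.searchsorted(tss_arr, peak.summit))
        # gather every gene achieving the minimal |summit - tss|; equal TSS
        # values sit in runs, so scan outward from the insertion point
        best: list[GeneAnnotation] = []
        best_dist: int | None = None
        for j in range(idx - 1, -1, -1):
            d = abs(peak.summit - tss_arr[j])
            if best_dist is not None and d > best_dist:
                break
            if best_dist is None or d < best_dist:
                best_dist, best = int(d), [genes[j]]
            else:
                best.append(genes[j])
        for j in range(idx, len(genes)):
            d = abs(peak.summit - tss_arr[j])
            if best_dist is not None and d > best_dist:
                break
            if best_dist is None or d < best_dist:
                best_dist, best = int(d), [genes[j]]
            else:
                best.append(genes[j])
        if best_dist is None or best_dist > max_distance:
            n_unlinked_far += 1
            continue
        if len(best) > 1:
            n_ties += 1
            best.sort(key=lambda g: g.gene_id)
            logger.warning(
                "peak %s:%d equidistant from %s; keeping %s",
                peak.chrom, peak.summit,
                ",".join(g.gene_id for g in best), best[0].gene_id,
            )
        gene = best[0]
        signed = peak.summit - gene.tss if gene.strand == "+" else gene.tss - peak.summit
        category = "promoter" if abs(signed) <= promoter_halfwidth else "distal"
        links.append(PeakGeneLink(peak, gene.gene_id, int(signed), category))
    if n_unlinked_chrom or n_unlinked_far:
        logger.info(
            "associate_peaks: %d peaks on unannotated chromosomes, %d beyond "
            "%d bp, %d ties", n_unlinked_chrom, n_unlinked_far, max_distance, n_ties,
        )
    return links


def bound_genes(links: Iterable[PeakGeneLink], tf: str) -> set[str]:
    """Deduplicated gene ids with at least one link for ``tf``."""
    return {l.gene_id for l in links if l.peak.tf == tf}


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _chi2_2x2(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on [[k1,n1-k1],[k2,n2-k2]]."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if np.any(expected == 0):  # degenerate margin: no evidence either way
        return 0.0, 1.0
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def binding_enrichment(geneset: set[str], background: set[str],
                       bound: set[str], *, set_name: str = "geneset",
                       tf: str = "TF") -> EnrichmentResult:
    """Test whether binding is enriched in ``geneset`` over ``background``.

    Chi-squared without continuity correction on the 2x2 table of
    bound/unbound x in-set/background; Fisher's exact p is computed
    alongside when any expected cell is below 5.
    """
    if not geneset:
        raise ValueError("empty gene set")
    if not background:
        raise ValueError("empty background")
    k_set, n_set = len(geneset & bound), len(geneset)
    k_bg, n_bg = len(background & bound), len(background)
    chi2, p = _chi2_2x2(k_set, n_set, k_bg, n_bg)
    table = np.array([[k_set, n_set - k_set], [k_bg, n_bg - k_bg]], dtype=float)
    n = table.sum()
    expected = table.sum(axis=1, keepdims=True) @ table.sum(axis=0, keepdims=True) / n
    fisher_p = None
    if np.any(expected < 5):
        fisher_p = float(stats.fisher_exact(table.astype(int))[1])
    return EnrichmentResult(set_name, tf, k_set, n_set, k_bg, n_bg, chi2, p, fisher_p)


def non_changing_background(de_tables: Iterable[DETable],
                            exclude: set[str] = frozenset(),
                            padj_floor: float = 0.5) -> set[str]:
    """Genes tested in every contrast with padj >= ``padj_floor`` throughout.

    Mirrors the "does not change in expression" background bars: a gene
    qualifies only if it was testable in all supplied contrasts and showed
    no hint of regulation in any of them; ``exclude`` (normally the gene
    set under test) is removed.
    """
    background: set[str] | None = None
    for table in de_tables:
        quiet = set(table.frame.index[table.frame["padj"] >= padj_floor])
        background = quiet if background is None else background & quiet
    if background is None:
        raise ValueError("no DE tables supplied")
    return background - set(exclude)


# ---------------------------------------------------------------------------
# CREs
# ---------------------------------------------------------------------------

def merge_cres(peaks_by_tf: Mapping[str, Sequence[Peak]],
               halfwidth: int = CRE_HALFWIDTH) -> list[CRE]:
    """Merge summit-centered windows across TFs into CREs.

    Every peak is trimmed to ``[summit - halfwidth, summit + halfwidth)``;
    overlapping windows (single linkage, across all TFs) form one CRE whose
    occupants are the union of contributing TF labels.  Output is sorted by
    (chrom, start) with pairwise-disjoint intervals.
    """
    windows = []
    for tf, peaks in peaks_by_tf.items():
        for p in peaks:
            windows.append((p.chrom, max(p.summit - halfwidth, 0),
                            p.summit + halfwidth, tf))
    windows.sort(key=lambda w: (w[0], w[1], w[2]))
    cres: list[CRE] = []
    cur = None  # [chrom, start, end, occupants, n_peaks]
    for chrom, start, end, tf in windows:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(tf)
            cur[4] += 1
        else:
            if cur is not None:
                cres.append(CRE(cur[0], cur[1], cur[2], frozenset(cur[3]), cur[4]))
            cur = [chrom, start, end, {tf}, 1]
    if cur is not None:
        cres.append(CRE(cur[0], cur[1], cur[2], frozenset(cur[3]), cur[4]))
    return cres


def link_cres(cres: Sequence[CRE], annotation: Sequence[GeneAnnotation],
              max_distance: int = MAX_DISTANCE) -> list[CRE]:
    """Attach the nearest-TSS gene (by CRE midpoint) to each CRE."""
    probes = [
        Peak(c.chrom, c.start, c.end, min(max(c.midpoint, c.start), c.end - 1),
             0.0, tf="__cre__", name=str(i))
        for i, c in enumerate(cres)
    ]
    links = {int(l.peak.name): l.gene_id
             for l in associate_peaks(probes, annotation, max_distance)}
    return [
        CRE(c.chrom, c.start, c.end, c.occupants, c.n_peaks, links.get(i))
        for i, c in enumerate(cres)
    ]


def sharing_fraction(cres: Sequence[CRE], tf_a: str, tf_b: str,
                     restrict_genes: set[str] | None = None) -> float:
    """Fraction of tf_a's CREs also occupied by tf_b (asymmetric).

    With ``restrict_genes``, only CREs linked to those genes are in scope.
    Returns NaN when tf_a occupies no CRE in scope.
    """
    in_scope = [
        c for c in cres
        if tf_a in c.occupants
        and (restrict_genes is None or c.gene_id in restrict_genes)
    ]
    if not in_scope:
        return float("nan")
    shared = sum(1 for c in in_scope if tf_b in c.occupants)
    return shared / len(in_scope)


def cres_per_gene(cres: Sequence[CRE], k: int = 3,
                  restrict_genes: set[str] | None = None) -> tuple[pd.Series, float]:
    """Distinct linked CREs per gene: (histogram, fraction of genes with >= k).

    Unlinked CREs are ignored.  The histogram is indexed by gene id; the
    fraction is NaN for empty input.
    """
    counts: dict[str, int] = {}
    for c in cres:
        if c.gene_id is None:
            continue
        if restrict_genes is not None and c.gene_id not in restrict_genes:
            continue
        counts[c.gene_id] = counts.get(c.gene_id, 0) + 1
    hist = pd.Series(counts, dtype=int).sort_index()
    hist.index.name = "gene_id"
    frac = float((hist >= k).mean()) if len(hist) else float("nan")
    return hist, frac


def activator_repressor_overlap(cres: Sequence[CRE], activators: set[str],
                                repressors: set[str]) -> dict[str, float]:
    """CRE- and gene-level co-occupancy between activator and repressor sets.

    Returns the four fractions the co-occupancy analysis reports:
    ``cre_activator_with_repressor`` (of activator-bound CREs, how many a
    repressor also occupies), its converse, and the same pair at gene level
    (a gene counts as activator/repressor-bound if any of its linked CREs
    is).  Fractions are NaN when the denominator is empty.
    """
    act_cres = [c for c in cres if c.occupants & activators]
    rep_cres = [c for c in cres if c.occupants & repressors]

    def _frac(num: int, den: int) -> float:
        return num / den if den else float("nan")

    cre_a_with_r = _frac(sum(1 for c in act_cres if c.occupants & repressors),
                         len(act_cres))
    cre_r_with_a = _frac(sum(1 for c in rep_cres if c.occupants & activators),
                         len(rep_cres))
    act_genes = {c.gene_id for c in act_cres if c.gene_id is not None}
    rep_genes = {c.gene_id for c in rep_cres if c.gene_id is not None}
    return {
        "cre_activator_with_repressor": cre_a_with_r,
        "cre_repressor_with_activator": cre_r_with_a,
        "gene_activator_with_repressor": _frac(len(act_genes & rep_genes),
                                               len(act_genes)),
        "gene_repressor_with_activator": _frac(len(rep_genes & act_genes),
                                               len(rep_genes)),
    }
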