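"""Readers/writers for counts, peaks, annotation and result tables.

This module is the single home for coordinate conventions: every genomic
interval in the package is 0-based, half-open ``[start, end)`` (the BED
dialect), and a gene's transcription start site (TSS) is ``body.start`` for
``+``-strand genes and ``body.end - 1`` (the last covered base) for
``-``-strand genes.  Gene identifiers are opaque strings.

Expression data travel as an :class:`ExpressionMatrix` — an integer
gene x sample count table plus one :class:`SampleMeta` per column describing
the progenitor-domain condition (dorsal, pMN, p3, FP, optionally with an
induced transcription factor), the time point in hours, and the replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "ExpressionMatrix",
    "Peak",
    "GeneAnnotation",
    "read_counts",
    "write_counts",
    "read_peaks",
    "write_peaks",
    "read_annotation",
    "write_annotation",
    "to_one_based_closed",
    "from_one_based_closed",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata for one column of the count matrix."""

    sample: str
    condition: str
    time_h: float
    replicate: int
    induced_tf: str | None = None
    induction_time_h: float | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample!r}: replicate must be >= 1")
        if self.induced_tf is not None:
            if self.induction_time_h is None:
                raise FormatError(
                    f"sample {self.sample!r}: induced_tf set without induction_time_h"
                )
            if self.induction_time_h > self.time_h:
                raise FormatError(
                    f"sample {self.sample!r}: induction_time_h ({self.induction_time_h}) "
                    f"> time_h ({self.time_h})"
                )


class ExpressionMatrix:
    """Integer gene x sample count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample; values must
        be non-negative integers.
    samples
        One :class:`SampleMeta` per column, matched by name (order-free).
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleMeta]):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        by_name = {s.sample: s for s in samples}
        if len(by_name) != len(samples):
            raise FormatError("duplicate sample names in metadata")
        missing = [c for c in counts.columns if c not in by_name]
        if missing:
            raise FormatError(f"unmatched sample(s) in counts header: {missing}")
        extra = [n for n in by_name if n not in counts.columns]
        if extra:
            raise FormatError(f"metadata sample(s) absent from counts: {extra}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(values < 0):
            raise FormatError("negative count encountered")
        if not np.allclose(values, np.round(values)):
            raise FormatError("non-integer count encountered")
        self.counts = counts.astype(np.int64)
        self.samples = [by_name[c] for c in counts.columns]

    # -- basic accessors ----------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    def meta(self, sample: str) -> SampleMeta:
        for s in self.samples:
            if s.sample == sample:
                return s
        raise KeyError(sample)

    def samples_for(self, condition: str, time_h: float | None = None) -> list[str]:
        """Sample names for a condition label, optionally at one time point."""
        return [
            s.sample
            for s in self.samples
            if s.condition == condition and (time_h is None or s.time_h == time_h)
        ]

    def subset(self, sample_names: Sequence[str]) -> "ExpressionMatrix":
        metas = [self.meta(n) for n in sample_names]
        return ExpressionMatrix(self.counts[list(sample_names)], metas)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    @property
    def times(self) -> list[float]:
        return sorted({s.time_h for s in self.samples})

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.samples]).set_index("sample")


@dataclass(frozen=True)
class Peak:
    """One TF binding interval with its summit (absolute coordinate)."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    tf: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end}: end <= start"
            )
        if not (self.start <= self.summit < self.end):
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} "
                "outside interval"
            )
        if self.score < 0:
            raise FormatError("peak score must be non-negative")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene with TSS and body interval; tss is strand-resolved (see module doc)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id}: empty body")
        expected = self.start if self.strand == "+" else self.end - 1
        if self.tss != expected:
            raise FormatError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with strand "
                f"{self.strand} body [{self.start},{self.end})"
            )


# ---------------------------------------------------------------------------
# coordinate conversion helpers (property-tested identity)
# ---------------------------------------------------------------------------

def to_one_based_closed(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based closed."""
    return start + 1, end


def from_one_based_closed(first: int, last: int) -> tuple[int, int]:
    """Convert a 1-based closed interval back to 0-based half-open."""
    return first - 1, last


# ---------------------------------------------------------------------------
# counts + metadata
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample count TSV and its sample-metadata TSV.

    The counts file has gene ids in the first column and one column per
    sample; the metadata file is keyed by sample name with columns
    ``sample, condition, time_h, replicate, induced_tf, induction_time_h``
    (the last two may be empty).
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample": str})
    required = {"sample", "condition", "time_h", "replicate"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata missing columns: {sorted(required - set(meta.columns))}")
    samples = []
    for row in meta.itertuples(index=False):
        induced = getattr(row, "induced_tf", None)
        if induced is not None and (pd.isna(induced) or induced == ""):
            induced = None
        t_ind = getattr(row, "induction_time_h", None)
        if t_ind is not None and pd.isna(t_ind):
            t_ind = None
        samples.append(
            SampleMeta(
                sample=str(row.sample),
                condition=str(row.condition),
                time_h=float(row.time_h),
                replicate=int(row.replicate),
                induced_tf=induced,
                induction_time_h=None if t_ind is None else float(t_ind),
            )
        )
    return ExpressionMatrix(counts, samples)


def write_counts(matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")
    meta = matrix.metadata_frame().reset_index()
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peaks (BED6 / ENCODE narrowPeak)
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, tf_label: str) -> list[Peak]:
    """Read peaks from BED6 or narrowPeak, sorted by (chrom, start).

    For narrowPeak the 10th column (summit offset from ``start``) is used
    when >= 0; otherwise — and for BED6 — the summit is the floor midpoint
    of the half-open interval.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 10):
                raise FormatError(
                    f"{path}:{lineno}: expected 6 (BED6) or 10 (narrowPeak) "
                    f"columns, got {len(fields)}"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            score = float(fields[4]) if fields[4] != "." else 0.0
            if len(fields) == 10 and int(fields[9]) >= 0:
                summit = start + int(fields[9])
            else:
                summit = (start + end - 1) // 2  # floor midpoint of [start, end)
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    score=score,
                    tf=tf_label,
                    name=fields[3],
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks in narrowPeak (BED6+4) with the summit in column 10."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        f"{p.score:g}",
                        ".",
                        "0",
                        "-1",
                        "-1",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the 5-column annotation TSV (gene_id, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation missing columns: {sorted(required - set(df.columns))}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicate gene_id in annotation: {dups[:5]}")
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        tss = start if row.strand == "+" else end - 1
        genes.append(
            GeneAnnotation(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=tss,
                start=start,
                end=end,
            )
        )
    return genes


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")
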