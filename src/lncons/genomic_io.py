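"""Core genomic primitives and file readers/writers shared by all pipeline stages.

All coordinates are internally 0-based, half-open (BED convention). GTF I/O
converts from/to the 1-based inclusive convention at the boundary, so reading
and re-writing a GTF is the identity on coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: Ensembl sub-biotypes collapsed onto the three-way vocabulary used here.
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "processed_transcript": "lncRNA",
    "3prime_overlapping_ncRNA": "lncRNA",
    "bidirectional_promoter_lncRNA": "lncRNA",
}


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


class ExpressionValidationError(ValueError):
    """Raised when an expression matrix violates its contract."""


@dataclass(frozen=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A stranded multi-exon transcript model.

    Exons are (start, end) pairs in ascending order, non-overlapping,
    0-based half-open on ``chrom``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: bad exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: invalid strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomeInterval:
        """Genomic region of the transcript: hull of its exons."""
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end (start on '+', end on '-')."""
        return self.start if self.strand != "-" else self.end

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


class AnnotationSet:
    """A collection of transcripts with per-chromosome interval indexes.

    Two indexes are maintained: one over exons (for exonic-overlap queries)
    and one over transcript spans (for region-overlap queries).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._transcripts: dict[str, TranscriptModel] = {}
        self._exon_index: dict[str, IntervalTree] = {}
        self._span_index: dict[str, IntervalTree] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        self._transcripts[t.transcript_id] = t
        exon_tree = self._exon_index.setdefault(t.chrom, IntervalTree())
        for s, e in t.exons:
            exon_tree.addi(s, e, t.transcript_id)
        span_tree = self._span_index.setdefault(t.chrom, IntervalTree())
        span_tree.addi(t.start, t.end, t.transcript_id)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._transcripts)

    def chroms(self) -> list[str]:
        return sorted(self._span_index)

    def exon_overlaps(self, chrom: str, start: int, end: int) -> set[str]:
        """Transcript ids with >=1 exonic base in [start, end) on chrom."""
        tree = self._exon_index.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def span_overlaps(self, chrom: str, start: int, end: int) -> set[str]:
        """Transcript ids whose span overlaps [start, end) on chrom."""
        tree = self._span_index.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(self._transcripts[i] for i in transcript_ids)

    def by_biotype(self, biotype: str) -> "AnnotationSet":
        return AnnotationSet(t for t in self if t.biotype == biotype)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def read_gtf(
    path,
    biotype_map: Mapping[str, str] | None = None,
) -> AnnotationSet:
    """Read an Ensembl-dialect GTF into an AnnotationSet.

    Only ``exon`` features are used; exons are grouped by ``transcript_id``.
    1-based inclusive GTF coordinates become 0-based half-open. The biotype
    is taken from ``transcript_biotype``/``gene_biotype`` attributes and
    collapsed through *biotype_map* (unknown values map to ``unknown``).
    """
    if biotype_map is None:
        biotype_map = DEFAULT_BIOTYPE_MAP
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 1 or end_i < start_i:
                raise GtfParseError(
                    f"{path}:{lineno}: bad GTF coordinates {start}-{end}"
                )
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                raise GtfParseError(f"{path}:{lineno}: exon without transcript_id")
            rec = per_tx.setdefault(
                tid,
                {
                    "gene_id": attr.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": "unknown",
                },
            )
            rec["exons"].append((start_i - 1, end_i))
            raw_biotype = attr.get("transcript_biotype") or attr.get("gene_biotype")
            if raw_biotype:
                rec["biotype"] = biotype_map.get(raw_biotype, "unknown")
    transcripts = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            biotype=rec["biotype"],
        )
        for tid, rec in per_tx.items()
    ]
    return AnnotationSet(transcripts)


def write_gtf(annotations: AnnotationSet, path, source: str = "lncons") -> None:
    """Write exon records in Ensembl GTF dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sorted(annotations, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            for s, e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


@dataclass
class ExpressionMatrix:
    """TPM expression values, features x samples, with sample metadata.

    ``sample_meta`` maps sample_id -> {"species": ..., "stage": ...}; either
    key may be absent when not applicable.
    """

    values: pd.DataFrame
    sample_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ExpressionValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ExpressionValidationError("duplicate sample ids")
        if self.values.size and (self.values.values < 0).any():
            raise ExpressionValidationError("negative expression values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def max_tpm(self, feature_id: str) -> float:
        """Max TPM across samples; 0.0 for features absent from the matrix."""
        if feature_id not in self.values.index:
            return 0.0
        if self.n_samples == 0:
            return 0.0
        return float(self.values.loc[feature_id].max())

    def summary(self, stat: str = "median") -> pd.Series:
        """Per-feature summary across samples (median or mean TPM)."""
        if stat not in ("median", "mean"):
            raise ValueError(f"unknown summary stat {stat!r}")
        return getattr(self.values, stat)(axis=1)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [f for f in feature_ids if f in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.sample_meta)

    def stages(self) -> dict[str, list[str]]:
        """Map stage label -> sample ids, in metadata order."""
        out: dict[str, list[str]] = {}
        for sid in self.sample_ids:
            meta = self.sample_meta.get(sid, {})
            stage = meta.get("stage")
            if stage is not None:
                out.setdefault(stage, []).append(sid)
        return out


def read_expression(path, meta_path=None) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature ids, header samples)
    and an optional sample-metadata TSV with columns sample_id, species, stage.

    Samples present in the matrix but absent from the metadata raise an
    error naming the sample; metadata rows for unknown samples are ignored
    with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    sample_meta: dict[str, dict] = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "sample_id" not in meta.columns:
            raise ExpressionValidationError(
                f"{meta_path}: metadata must have a sample_id column"
            )
        for _, row in meta.iterrows():
            sid = row["sample_id"]
            if sid not in df.columns:
                logger.warning("metadata sample %s not in matrix; ignored", sid)
                continue
            sample_meta[sid] = {
                k: row[k] for k in ("species", "stage") if k in meta.columns
            }
        missing = [s for s in df.columns if s not in sample_meta]
        if missing:
            raise ExpressionValidationError(
                f"samples missing from metadata: {missing}"
            )
    return ExpressionMatrix(df.astype(float) if df.size else df, sample_meta)


def write_expression(expr: ExpressionMatrix, path, meta_path=None) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.6g", index_label="feature_id")
    if meta_path is not None:
        rows = []
        for sid in expr.sample_ids:
            meta = expr.sample_meta.get(sid, {})
            rows.append(
                {
                    "sample_id": sid,
                    "species": meta.get("species", ""),
                    "stage": meta.get("stage", ""),
                }
            )
        pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def read_bedgraph(path) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome (starts, ends, values) arrays.

    Returns a dict chrom -> structured array sorted by start. Intervals are
    assumed non-overlapping within a chromosome (standard for score tracks).
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            per_chrom.setdefault(chrom, []).append((start, end, value))
    out = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        arr = np.array(rows, dtype=[("start", "i8"), ("end", "i8"), ("value", "f8")])
        out[chrom] = arr
    return out


def write_bedgraph(per_chrom: Mapping[str, Iterable[tuple[int, int, float]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(per_chrom):
            for start, end, value in per_chrom[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")
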