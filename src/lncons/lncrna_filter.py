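"""Transcript classification, the lncRNA filter cascade, and family grouping.

The cascade keeps a transcript as a high-confidence lncRNA iff:

* spliced length >= 200 bases (the standard lncRNA length definition),
* coding-potential score <= 0.5,
* expressed (max TPM across samples > 0), and
* class is a known lncRNA match or a multi-exon novel transcript —
  transcripts overlapping protein-coding exons, antisense overlaps of any
  annotation, and unannotated single-exon transcripts are removed.

Boundary semantics are inclusive on the keep side: length exactly 200 and
score exactly 0.5 are kept. The removal reason records the first failing
rule in the order length, coding, expression, class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genomic_io import AnnotationSet, ExpressionMatrix, GenomeInterval, TranscriptModel

logger = logging.getLogger(__name__)

# transcript classes
KNOWN_LNCRNA_MATCH = "known_lncrna_match"
PCG_OVERLAP = "pcg_overlap"
ANTISENSE_OVERLAP = "antisense_overlap"
SINGLE_EXON_NOVEL = "single_exon_novel"
MULTI_EXON_NOVEL = "multi_exon_novel"

KEPT_CLASSES = frozenset({KNOWN_LNCRNA_MATCH, MULTI_EXON_NOVEL})

# removal reasons, in cascade order
TOO_SHORT = "too_short"
CODING = "coding"
NOT_EXPRESSED = "not_expressed"
CLASS_REMOVED = "class_removed"


@dataclass
class FilterParams:
    min_length: int = 200
    max_coding_potential: float = 0.5
    min_tpm: float = 0.0  # exclusive: max TPM must be strictly greater


@dataclass
class FilterRecord:
    transcript_id: str
    spliced_length: int
    coding_potential: float
    max_tpm: float
    transcript_class: str
    kept: bool
    removal_reason: str = ""


@dataclass
class FilterReport:
    records: list[FilterRecord]

    @property
    def kept_ids(self) -> list[str]:
        return [r.transcript_id for r in self.records if r.kept]

    @property
    def n_removed(self) -> int:
        return sum(not r.kept for r in self.records)

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            if not r.kept:
                out[r.removal_reason] = out.get(r.removal_reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass
class LncRnaFamily:
    """A locus-level unit: same-strand isoforms whose spans overlap."""

    family_id: str
    member_transcript_ids: set[str]
    span: GenomeInterval
    strand: str


def _same_strand_exonic_overlap(
    t: TranscriptModel, ref: AnnotationSet, biotype: str | None, same_strand: bool
) -> bool:
    hits: set[str] = set()
    for s, e in t.exons:
        hits |= ref.exon_overlaps(t.chrom, s, e)
    for hid in hits:
        r = ref[hid]
        strand_ok = (r.strand == t.strand) if same_strand else (
            r.strand != t.strand and r.strand in "+-" and t.strand in "+-"
        )
        if not strand_ok:
            continue
        if biotype is not None and r.biotype != biotype:
            continue
        # require exon-to-exon overlap, not just exon-vs-span
        for rs, re_ in r.exons:
            if any(s < re_ and rs < e for s, e in t.exons):
                return True
    return False


def classify_transcript(t: TranscriptModel, ref: AnnotationSet) -> str:
    """Classify a transcript against a reference annotation.

    Precedence: same-strand exonic overlap with a protein-coding reference
    transcript, then with a reference lncRNA, then opposite-strand exonic
    overlap with any reference transcript, then novel single-/multi-exon.
    Intron-contained transcripts (no exonic overlap) fall through to the
    novel classes.
    """
    if t.chrom not in ref.chroms():
        logger.debug("chrom %s absent from reference; novel classes only", t.chrom)
    if _same_strand_exonic_overlap(t, ref, "protein_coding", same_strand=True):
        return PCG_OVERLAP
    if _same_strand_exonic_overlap(t, ref, "lncRNA", same_strand=True):
        return KNOWN_LNCRNA_MATCH
    if _same_strand_exonic_overlap(t, ref, None, same_strand=False):
        return ANTISENSE_OVERLAP
    if t.n_exons == 1:
        return SINGLE_EXON_NOVEL
    return MULTI_EXON_NOVEL


def filter_lncrna_candidates(
    transcripts: Iterable[TranscriptModel],
    coding_scores: Mapping[str, float],
    expr: ExpressionMatrix,
    ref: AnnotationSet,
    params: FilterParams | None = None,
) -> tuple[list[TranscriptModel], FilterReport]:
    """Apply the filter cascade; returns (kept transcripts, full report).

    Every transcript must have a coding score; transcripts absent from the
    expression matrix count as max TPM 0 (not expressed).
    """
    if params is None:
        params = FilterParams()
    kept: list[TranscriptModel] = []
    records: list[FilterRecord] = []
    for t in transcripts:
        if t.transcript_id not in coding_scores:
            raise KeyError(f"no coding-potential score for {t.transcript_id}")
        score = float(coding_scores[t.transcript_id])
        max_tpm = expr.max_tpm(t.transcript_id)
        tclass = classify_transcript(t, ref)
        reason = ""
        if t.spliced_length < params.min_length:
            reason = TOO_SHORT
        elif score > params.max_coding_potential:
            reason = CODING
        elif not max_tpm > params.min_tpm:
            reason = NOT_EXPRESSED
        elif tclass not in KEPT_CLASSES:
            reason = CLASS_REMOVED
        record = FilterRecord(
            transcript_id=t.transcript_id,
            spliced_length=t.spliced_length,
            coding_potential=score,
            max_tpm=max_tpm,
            transcript_class=tclass,
            kept=reason == "",
            removal_reason=reason,
        )
        records.append(record)
        if record.kept:
            kept.append(t)
    kept = deduplicate_intron_chains(kept, ref)
    kept_ids = {t.transcript_id for t in kept}
    for r in records:
        if r.kept and r.transcript_id not in kept_ids:
            r.kept = False
            r.removal_reason = "duplicate_intron_chain"
    return kept, FilterReport(records)


def deduplicate_intron_chains(
    transcripts: list[TranscriptModel], ref: AnnotationSet
) -> list[TranscriptModel]:
    """Collapse multi-exon transcripts with identical intron chains on the
    same chrom/strand, preferring ids present in the reference annotation."""
    seen: dict[tuple, TranscriptModel] = {}
    out: list[TranscriptModel] = []
    for t in transcripts:
        if t.n_exons == 1:
            out.append(t)
            continue
        key = (t.chrom, t.strand, t.intron_chain())
        prev = seen.get(key)
        if prev is None:
            seen[key] = t
        elif t.transcript_id in ref and prev.transcript_id not in ref:
            seen[key] = t
    out.extend(seen.values())
    order = {t.transcript_id: i for i, t in enumerate(transcripts)}
    out.sort(key=lambda t: order[t.transcript_id])
    return out


def group_families(
    transcripts: Iterable[TranscriptModel], prefix: str = "FAM"
) -> list[LncRnaFamily]:
    """Single-linkage grouping of transcripts whose genomic spans overlap
    (>= 1 base) on the same chromosome and strand.

    Isoforms located in the same genomic region form one family; the family
    span is the hull of the member spans. Families are numbered in genomic
    order per strand.
    """
    txs = sorted(transcripts, key=lambda t: (t.chrom, t.strand, t.start, t.end))
    families: list[LncRnaFamily] = []
    cluster: list[TranscriptModel] = []

    def flush() -> None:
        if not cluster:
            return
        span = GenomeInterval(
            cluster[0].chrom,
            min(t.start for t in cluster),
            max(t.end for t in cluster),
            cluster[0].strand,
        )
        families.append(
            LncRnaFamily(
                family_id="",
                member_transcript_ids={t.transcript_id for t in cluster},
                span=span,
                strand=cluster[0].strand,
            )
        )
        cluster.clear()

    cur_end = -1
    for t in txs:
        if (
            cluster
            and t.chrom == cluster[0].chrom
            and t.strand == cluster[0].strand
            and t.start < cur_end
        ):
            cluster.append(t)
            cur_end = max(cur_end, t.end)
        else:
            flush()
            cluster.append(t)
            cur_end = t.end
    flush()
    families.sort(key=lambda f: (f.span.chrom, f.span.start, f.strand))
    for i, fam in enumerate(families, start=1):
        fam.family_id = f"{prefix}{i:04d}"
    return families


def family_lookup(families: Iterable[LncRnaFamily]) -> dict[str, str]:
    """Map member transcript_id -> family_id."""
    out: dict[str, str] = {}
    for fam in families:
        for tid in fam.member_transcript_ids:
            out[tid] = fam.family_id
    return out
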