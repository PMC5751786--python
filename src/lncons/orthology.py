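"""Cross-genome pairing of lncRNAs from lifted coordinates, conservation
summaries, and cross-species expression correlation.

A genome-B lncRNA located within or overlapping the lifted (orthologous)
region of a genome-A lncRNA forms a conserved pair with it. Pairing is
many-to-many and strand-agnostic (the lifted strand depends on chain
orientation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .chain_liftover import LiftResult
from .genomic_io import AnnotationSet, ExpressionMatrix, GenomeInterval
from .lncrna_filter import LncRnaFamily, family_lookup


@dataclass(frozen=True)
class ConservedPair:
    a_transcript_id: str
    b_transcript_id: str
    lifted_region: GenomeInterval
    overlap_bases: int

    def __post_init__(self) -> None:
        if self.overlap_bases < 1:
            raise ValueError("conserved pair requires >= 1 overlapping base")


@dataclass
class ConservationSummary:
    n_a_conserved: int
    n_b_conserved: int
    n_a_families: int
    pairs_by_family: dict[str, list[ConservedPair]]


def pair_conserved(
    lifted: Mapping[str, LiftResult],
    b_lncrnas: AnnotationSet,
    min_overlap: int = 1,
) -> list[ConservedPair]:
    """Pair each successfully lifted genome-A lncRNA with every genome-B
    lncRNA whose transcript span overlaps the lifted region by at least
    *min_overlap* bases. Only transcripts with biotype lncRNA are eligible
    on the B side."""
    pairs: list[ConservedPair] = []
    for a_id in sorted(lifted):
        result = lifted[a_id]
        if result.status != "mapped" or result.mapped is None:
            continue
        region = result.mapped
        for b_id in sorted(b_lncrnas.span_overlaps(region.chrom, region.start, region.end)):
            b = b_lncrnas[b_id]
            if b.biotype != "lncRNA":
                continue
            overlap = min(region.end, b.end) - max(region.start, b.start)
            if overlap >= min_overlap:
                pairs.append(ConservedPair(a_id, b_id, region, overlap))
    return pairs


def summarize_conservation(
    pairs: Iterable[ConservedPair], a_families: Iterable[LncRnaFamily]
) -> ConservationSummary:
    """Distinct conserved transcript counts on both sides plus the
    family-level rollup (a family is conserved if >= 1 member is)."""
    pairs = list(pairs)
    fam_of = family_lookup(a_families)
    a_ids = {p.a_transcript_id for p in pairs}
    b_ids = {p.b_transcript_id for p in pairs}
    by_family: dict[str, list[ConservedPair]] = {}
    for p in pairs:
        fam = fam_of.get(p.a_transcript_id)
        if fam is None:
            raise ValueError(
                f"pair references {p.a_transcript_id}, which is in no family"
            )
        by_family.setdefault(fam, []).append(p)
    return ConservationSummary(
        n_a_conserved=len(a_ids),
        n_b_conserved=len(b_ids),
        n_a_families=len(by_family),
        pairs_by_family=by_family,
    )


def cross_species_expression_correlation(
    pairs: Iterable[tuple[str, str]],
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    summary_stat: str = "median",
) -> tuple[float, int]:
    """Spearman correlation of per-feature summary expression across
    conserved pairs.

    For each (a, b) pair the summary statistic (median or mean TPM) is taken
    across each species' own samples; the rank correlation is computed over
    pairs. Returns (rho, n_pairs_used). Pairs whose features are missing
    from either matrix are dropped.
    """
    sa = expr_a.summary(summary_stat)
    sb = expr_b.summary(summary_stat)
    xs, ys = [], []
    for a_id, b_id in pairs:
        if a_id in sa.index and b_id in sb.index:
            xs.append(sa[a_id])
            ys.append(sb[b_id])
    if len(xs) < 3:
        raise ValueError(f"need >= 3 pairs for a correlation, got {len(xs)}")
    rho, _ = stats.spearmanr(xs, ys)
    return float(rho), len(xs)


def correlation_by_class(
    pairs_by_class: Mapping[str, Iterable[tuple[str, str]]],
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    summary_stat: str = "median",
) -> dict[str, tuple[float, int]]:
    """Cross-species correlation reported separately per gene class
    (e.g. lncRNA pairs vs protein-coding pairs)."""
    return {
        cls: cross_species_expression_correlation(ps, expr_a, expr_b, summary_stat)
        for cls, ps in pairs_by_class.items()
    }


def pairs_to_frame(pairs: Iterable[ConservedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "a_transcript_id": p.a_transcript_id,
                "b_transcript_id": p.b_transcript_id,
                "chrom": p.lifted_region.chrom,
                "lifted_start": p.lifted_region.start,
                "lifted_end": p.lifted_region.end,
                "overlap_bases": p.overlap_bases,
            }
            for p in pairs
        ],
        columns=[
            "a_transcript_id",
            "b_transcript_id",
            "chrom",
            "lifted_start",
            "lifted_end",
            "overlap_bases",
        ],
    )
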