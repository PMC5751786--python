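"""Bidirectional (divergent) lncRNA-protein-coding gene pairs and their
conservation in a second genome.

A divergent pair shares a putative bidirectional promoter: the two
transcripts lie on opposite strands, head-to-head (the '-' element 5'-ward
of the '+' element), with their transcription start sites at most
``max_dist`` bases apart (2000 by default) and no other transcript's TSS
between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genomic_io import AnnotationSet, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BidirectionalPair:
    lncrna_id: str
    pcg_id: str
    tss_distance: int
    genome: str = "A"


def _divergent(
    minus: TranscriptModel, plus: TranscriptModel, max_dist: int, allow_overlap: bool
) -> int | None:
    """TSS distance if (minus, plus) form a divergent pair, else None."""
    if minus.chrom != plus.chrom:
        return None
    dist = plus.tss - minus.tss
    if dist < 0 and not allow_overlap:
        return None
    if abs(dist) > max_dist:
        return None
    return dist


def find_bidirectional_pairs(
    lncrnas: AnnotationSet,
    pcgs: AnnotationSet,
    max_dist: int = 2000,
    allow_overlap: bool = False,
    genome: str = "A",
) -> list[BidirectionalPair]:
    """All divergent lncRNA-PCG pairs within *max_dist* (TSS to TSS,
    boundary inclusive).

    Adjacency is enforced: no transcript from either set may have its TSS
    strictly between the pair's TSSs.
    """
    all_tss: list[tuple[str, int]] = [
        (t.chrom, t.tss) for t in list(lncrnas) + list(pcgs)
    ]

    def intervening(chrom: str, lo: int, hi: int, own: set[int]) -> bool:
        return any(c == chrom and lo < pos < hi for c, pos in all_tss
                   if pos not in own)

    pairs: list[BidirectionalPair] = []
    for lnc in lncrnas:
        if lnc.strand not in "+-":
            continue
        for pcg in pcgs:
            if pcg.strand not in "+-" or pcg.strand == lnc.strand:
                continue
            minus, plus = (lnc, pcg) if lnc.strand == "-" else (pcg, lnc)
            dist = _divergent(minus, plus, max_dist, allow_overlap)
            if dist is None:
                continue
            lo, hi = sorted((minus.tss, plus.tss))
            if intervening(lnc.chrom, lo, hi, {minus.tss, plus.tss}):
                continue
            pairs.append(
                BidirectionalPair(
                    lncrna_id=lnc.transcript_id,
                    pcg_id=pcg.transcript_id,
                    tss_distance=dist,
                    genome=genome,
                )
            )
    pairs.sort(key=lambda p: (p.lncrna_id, p.pcg_id))
    return pairs


def conserved_neighbor_check(
    pairs_a: Iterable[BidirectionalPair],
    conserved_lnc_pairs: Iterable[tuple[str, str]],
    pcg_orthologs: Mapping[str, str],
    lncrnas_b: AnnotationSet,
    pcgs_b: AnnotationSet,
    max_dist: int = 2000,
) -> list[tuple[BidirectionalPair, BidirectionalPair]]:
    """Genome-A divergent pairs whose lncRNA has a conserved genome-B
    partner forming a divergent pair with the orthologous PCG.

    PCGs without an ortholog entry are treated as non-conserved and logged.
    Returns (A pair, matching B pair) tuples.
    """
    partners: dict[str, set[str]] = {}
    for a_id, b_id in conserved_lnc_pairs:
        partners.setdefault(a_id, set()).add(b_id)
    pairs_b = find_bidirectional_pairs(lncrnas_b, pcgs_b, max_dist=max_dist, genome="B")
    b_index = {(p.lncrna_id, p.pcg_id): p for p in pairs_b}
    out: list[tuple[BidirectionalPair, BidirectionalPair]] = []
    for pa in pairs_a:
        b_pcg = pcg_orthologs.get(pa.pcg_id)
        if b_pcg is None:
            logger.info("PCG %s has no ortholog entry; pair not conserved", pa.pcg_id)
            continue
        for b_lnc in sorted(partners.get(pa.lncrna_id, ())):
            pb = b_index.get((b_lnc, b_pcg))
            if pb is not None:
                out.append((pa, pb))
    return out


def pairs_to_frame(pairs: Iterable[BidirectionalPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(p) for p in pairs],
        columns=["lncrna_id", "pcg_id", "tss_distance", "genome"],
    )
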