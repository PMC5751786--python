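"""Per-base conservation scoring of transcripts and group comparisons.

Scores come from a PhastCons-like track (bedGraph): per-base conservation
probabilities in [0, 1]. A transcript's score is the mean over its exonic
bases that carry a score; unscored bases are excluded from both numerator
and denominator (conservation tracks are sparse).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_io import AnnotationSet, GenomeInterval, TranscriptModel, read_bedgraph


class UndefinedScoreError(ValueError):
    """No scored bases fall inside the queried region."""


class ScoreTrack:
    """Sparse per-base score track held as non-overlapping scored intervals."""

    def __init__(self, per_chrom: Mapping[str, np.ndarray]) -> None:
        # each value: structured array with fields start, end, value, sorted
        self._per_chrom = dict(per_chrom)
        for chrom, arr in self._per_chrom.items():
            if arr.size and ((arr["value"] < 0).any() or (arr["value"] > 1).any()):
                raise ValueError(f"{chrom}: scores outside [0, 1]")

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        return cls(read_bedgraph(path))

    def region_sum(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """(sum of per-base scores, number of scored bases) in [start, end)."""
        arr = self._per_chrom.get(chrom)
        if arr is None or arr.size == 0:
            return 0.0, 0
        lo = np.searchsorted(arr["end"], start, side="right")
        hi = np.searchsorted(arr["start"], end, side="left")
        if lo >= hi:
            return 0.0, 0
        seg = arr[lo:hi]
        overlap = np.minimum(seg["end"], end) - np.maximum(seg["start"], start)
        overlap = np.clip(overlap, 0, None)
        return float(np.sum(overlap * seg["value"])), int(overlap.sum())


def transcript_score(t: TranscriptModel, track: ScoreTrack) -> float:
    """Mean conservation score over the transcript's scored exonic bases."""
    total, n = 0.0, 0
    for s, e in t.exons:
        part_sum, part_n = track.region_sum(t.chrom, s, e)
        total += part_sum
        n += part_n
    if n == 0:
        raise UndefinedScoreError(
            f"{t.transcript_id}: no scored bases in any exon"
        )
    return total / n


def interval_score(iv: GenomeInterval, track: ScoreTrack) -> float:
    """Mean conservation score over the scored bases of one interval."""
    total, n = track.region_sum(iv.chrom, iv.start, iv.end)
    if n == 0:
        raise UndefinedScoreError(f"no scored bases in {iv}")
    return total / n


def score_transcripts(
    transcripts: Iterable[TranscriptModel], track: ScoreTrack
) -> tuple[dict[str, float], list[str]]:
    """Batch scoring; transcripts with no scored bases are skipped and
    returned separately rather than aborting the batch."""
    scores: dict[str, float] = {}
    skipped: list[str] = []
    for t in transcripts:
        try:
            scores[t.transcript_id] = transcript_score(t, track)
        except UndefinedScoreError:
            skipped.append(t.transcript_id)
    return scores, skipped


def sample_random_regions(
    genome_sizes: Mapping[str, int],
    template_lengths: Sequence[int],
    n: int,
    seed: int,
    exclusions: AnnotationSet | None = None,
    max_attempts_factor: int = 100,
) -> list[GenomeInterval]:
    """Random background intervals with lengths resampled from
    *template_lengths*, placed uniformly, rejecting overlaps with
    *exclusions* (transcript spans). Deterministic under *seed*."""
    if not template_lengths:
        raise ValueError("template_lengths must be non-empty")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome_sizes)
    weights = np.array([genome_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[GenomeInterval] = []
    attempts = 0
    max_attempts = max(n * max_attempts_factor, 1000)
    while len(out) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {len(out)}/{n} random regions after "
                f"{attempts} attempts; exclusions too dense"
            )
        attempts += 1
        length = int(rng.choice(template_lengths))
        chrom = str(rng.choice(chroms, p=weights))
        limit = genome_sizes[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if exclusions is not None and exclusions.span_overlaps(
            chrom, start, start + length
        ):
            continue
        out.append(GenomeInterval(chrom, start, start + length, "."))
    return out


@dataclass
class GroupComparison:
    groups: list[str]
    medians: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]  # (a, b): P(one-sided, a > b)


def compare_groups(scores_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Pairwise one-sided Wilcoxon rank-sum tests between score groups.

    For each ordered pair (a, b), the p-value tests the alternative that
    group a's scores are stochastically greater than group b's.
    """
    groups = list(scores_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in scores_by_group.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has {len(v)} < 3 scores")
    medians = {g: float(np.median(scores_by_group[g])) for g in groups}
    pairwise: dict[tuple[str, str], float] = {}
    for a in groups:
        for b in groups:
            if a == b:
                continue
            stat = stats.mannwhitneyu(
                scores_by_group[a], scores_by_group[b], alternative="greater"
            )
            pairwise[(a, b)] = float(stat.pvalue)
    return GroupComparison(groups=groups, medians=medians, pairwise_p=pairwise)
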