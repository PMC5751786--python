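"""Temporal expression trend classification over ordered developmental
stages (rat brain at weeks 2, 6, 21 and 104 in the motivating study), and
mapping of trends onto cross-species partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genomic_io import ExpressionMatrix

DEFAULT_STAGES = ("W2", "W6", "W21", "W104")

UP = "up"
DOWN = "down"
NONE = "none"
MIXED = "mixed"


@dataclass
class StageProfile:
    transcript_id: str
    stages: tuple[str, ...]
    stage_means: np.ndarray  # mean TPM per stage, chronological order

    def __post_init__(self) -> None:
        self.stage_means = np.asarray(self.stage_means, dtype=float)
        if len(self.stage_means) != len(self.stages):
            raise ValueError("stage_means must align with stages")
        if (self.stage_means < 0).any():
            raise ValueError("stage means must be non-negative")


@dataclass(frozen=True)
class TrendCall:
    transcript_id: str
    trend: str  # up | down | none


def stage_expression(
    expr: ExpressionMatrix, stages: Sequence[str] = DEFAULT_STAGES
) -> list[StageProfile]:
    """Per-transcript mean TPM per developmental stage.

    Every sample must carry a stage label from *stages* and every stage
    must have at least one sample.
    """
    by_stage = expr.stages()
    for sid in expr.sample_ids:
        if expr.sample_meta.get(sid, {}).get("stage") is None:
            raise ValueError(f"sample {sid} has no stage label")
    missing = [s for s in stages if not by_stage.get(s)]
    if missing:
        raise ValueError(f"stages with no samples: {missing}")
    mean_by_stage = {
        s: expr.values[by_stage[s]].mean(axis=1) for s in stages
    }
    profiles = []
    for tid in expr.feature_ids:
        means = np.array([mean_by_stage[s][tid] for s in stages])
        profiles.append(
            StageProfile(transcript_id=tid, stages=tuple(stages), stage_means=means)
        )
    return profiles


def classify_trend(profile: StageProfile, min_ratio: float = 1.0) -> TrendCall:
    """Monotone trend call over the stage means.

    ``up`` iff each stage mean exceeds the previous one by the fold margin
    (m[t+1] > m[t] * min_ratio for all consecutive stages); ``down`` iff
    each falls below the previous by the same margin; otherwise ``none``.
    The default margin 1.0 is strict monotonicity, so ties break a trend.
    """
    m = profile.stage_means
    up = all(m[i + 1] > m[i] * min_ratio for i in range(len(m) - 1))
    down = all(m[i + 1] * min_ratio < m[i] for i in range(len(m) - 1))
    if up:
        trend = UP
    elif down:
        trend = DOWN
    else:
        trend = NONE
    return TrendCall(transcript_id=profile.transcript_id, trend=trend)


def classify_trends(
    expr: ExpressionMatrix,
    stages: Sequence[str] = DEFAULT_STAGES,
    min_ratio: float = 1.0,
) -> list[TrendCall]:
    return [
        classify_trend(p, min_ratio=min_ratio)
        for p in stage_expression(expr, stages)
    ]


def map_trends_to_partner(
    calls: Iterable[TrendCall],
    conserved_pairs: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Attach genome-B trend calls to their conserved genome-A partners.

    Each genome-A lncRNA with >= 1 partner carrying a call is listed with
    the shared trend, or ``mixed`` when partners disagree (ignoring
    ``none`` partners unless all are ``none``). A lncRNAs with no called
    partner are absent from the table.
    """
    call_of = {c.transcript_id: c.trend for c in calls}
    partner_trends: dict[str, list[str]] = {}
    for a_id, b_id in conserved_pairs:
        if b_id in call_of:
            partner_trends.setdefault(a_id, []).append(call_of[b_id])
    rows = []
    for a_id in sorted(partner_trends):
        trends = partner_trends[a_id]
        directional = {t for t in trends if t in (UP, DOWN)}
        if len(directional) > 1:
            trend = MIXED
        elif directional:
            trend = directional.pop()
        else:
            trend = NONE
        rows.append({"a_transcript_id": a_id, "trend": trend,
                     "n_partners": len(trends)})
    return pd.DataFrame(rows, columns=["a_transcript_id", "trend", "n_partners"])


def trend_counts(calls: Iterable[TrendCall]) -> dict[str, int]:
    out = {UP: 0, DOWN: 0, NONE: 0}
    for c in calls:
        out[c.trend] += 1
    return out
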