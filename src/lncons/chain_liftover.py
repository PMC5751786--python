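"""UCSC chain parsing and liftOver-style interval mapping.

A chain aligns a *target* genome (the source of the coordinates being
lifted, ``t`` header fields, always '+' strand) to a *query* genome (the
destination, ``q`` fields, '+' or '-'). Query coordinates of a '-'-strand
chain are stored on the reversed strand, per the UCSC convention, and are
converted to forward-strand coordinates only when a result is emitted.

``lift_interval`` reproduces liftOver's default behaviour: an interval maps
when a single best chain carries at least ``min_match`` of its bases
(default 0.95); a second chain reaching ``min_match`` makes the result
ambiguous; anything in between is partial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .genomic_io import GenomeInterval, TranscriptModel


class ChainFormatError(ValueError):
    """Raised when a chain file violates the UCSC format invariants."""


@dataclass(frozen=True)
class ChainBlock:
    """One gapless aligned block: ``size`` bases, then gaps ``dt`` on the
    target and ``dq`` on the query before the next block (0 for the last)."""

    size: int
    dt: int = 0
    dq: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ChainFormatError(f"block size must be positive, got {self.size}")
        if self.dt < 0 or self.dq < 0:
            raise ChainFormatError("block gaps must be non-negative")


@dataclass
class Chain:
    """One net alignment between a target and a query genome."""

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[ChainBlock]
    chain_id: str = ""

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise ChainFormatError(
                f"chain {self.chain_id}: target strand must be '+' (UCSC convention)"
            )
        if self.q_strand not in ("+", "-"):
            raise ChainFormatError(f"chain {self.chain_id}: bad query strand")
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: blocks span {t_span} target bases but "
                f"header declares {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: blocks span {q_span} query bases but "
                f"header declares {self.q_end - self.q_start}"
            )
        last = self.blocks[-1]
        if last.dt != 0 or last.dq != 0:
            raise ChainFormatError(
                f"chain {self.chain_id}: final block must have zero gaps"
            )

    def block_coords(self) -> Iterable[tuple[int, int, int]]:
        """Yield (t_block_start, q_block_start, size) for each block.

        Query starts are on the chain's own strand (reversed coordinates
        for a '-'-strand chain).
        """
        tpos, qpos = self.t_start, self.q_start
        for b in self.blocks:
            yield tpos, qpos, b.size
            tpos += b.size + b.dt
            qpos += b.size + b.dq


@dataclass
class LiftResult:
    """Outcome of lifting one interval through the chain set."""

    status: str  # mapped | partial | unmapped | ambiguous
    mapped: GenomeInterval | None = None
    match_fraction: float = 0.0
    chain_id: str = ""
    blocks: list[GenomeInterval] = field(default_factory=list)


def read_chain(path) -> list[Chain]:
    """Parse a UCSC chain file (header lines + block lines, blank-separated)."""
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, *rest) = header
        chains.append(
            Chain(
                score=float(score),
                t_name=t_name,
                t_size=int(t_size),
                t_strand=t_strand,
                t_start=int(t_start),
                t_end=int(t_end),
                q_name=q_name,
                q_size=int(q_size),
                q_strand=q_strand,
                q_start=int(q_start),
                q_end=int(q_end),
                blocks=blocks,
                chain_id=rest[0] if rest else "",
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                finish()
                continue
            if line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                header = line.split()
                if len(header) < 12:
                    raise ChainFormatError(f"{path}:{lineno}: short chain header")
                continue
            if header is None:
                raise ChainFormatError(f"{path}:{lineno}: block outside a chain")
            parts = line.split()
            if len(parts) == 1:
                blocks.append(ChainBlock(int(parts[0]), 0, 0))
            elif len(parts) == 3:
                blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
            else:
                raise ChainFormatError(f"{path}:{lineno}: bad block line")
    finish()
    return chains


def write_chain(chains: Iterable[Chain], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            score = int(c.score) if float(c.score).is_integer() else c.score
            fh.write(
                f"chain {score} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for i, b in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{b.size}\n")
                else:
                    fh.write(f"{b.size}\t{b.dt}\t{b.dq}\n")
            fh.write("\n")


def invert_chain(chain: Chain) -> Chain:
    """Swap target and query so the chain lifts in the opposite direction.

    The inverted chain's target is the old query on its forward strand; when
    the original query strand is '-', block order reverses and the old
    target coordinates are re-expressed on its reversed strand.
    """
    if chain.q_strand == "+":
        blocks = [ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks]
        return Chain(
            score=chain.score,
            t_name=chain.q_name, t_size=chain.q_size, t_strand="+",
            t_start=chain.q_start, t_end=chain.q_end,
            q_name=chain.t_name, q_size=chain.t_size, q_strand="+",
            q_start=chain.t_start, q_end=chain.t_end,
            blocks=blocks,
            chain_id=chain.chain_id,
        )
    # '-' query: reverse block order; the gap after a block in the new order
    # is the gap that preceded it in the old order, with dt/dq swapped.
    n = len(chain.blocks)
    new_blocks = []
    for j in range(n):
        k = n - 1 - j  # original index of the j-th block in the new order
        if j == n - 1:
            new_blocks.append(ChainBlock(chain.blocks[k].size, 0, 0))
        else:
            prev = chain.blocks[k - 1]  # next block in new order is k-1
            new_blocks.append(ChainBlock(chain.blocks[k].size, prev.dq, prev.dt))
    return Chain(
        score=chain.score,
        t_name=chain.q_name, t_size=chain.q_size, t_strand="+",
        t_start=chain.q_size - chain.q_end,
        t_end=chain.q_size - chain.q_start,
        q_name=chain.t_name, q_size=chain.t_size, q_strand="-",
        q_start=chain.t_size - chain.t_end,
        q_end=chain.t_size - chain.t_start,
        blocks=new_blocks,
        chain_id=chain.chain_id,
    )


class ChainIndex:
    """Chains grouped by target chromosome for overlap lookup."""

    def __init__(self, chains: Iterable[Chain]) -> None:
        self._by_chrom: dict[str, list[Chain]] = {}
        for c in chains:
            self._by_chrom.setdefault(c.t_name, []).append(c)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Chain]:
        return [
            c
            for c in self._by_chrom.get(chrom, [])
            if c.t_start < end and start < c.t_end
        ]


def _map_through_chain(
    iv: GenomeInterval, chain: Chain
) -> tuple[int, list[tuple[int, int]]]:
    """Map iv through one chain.

    Returns (n_mapped_bases, destination segments) where segments are
    forward-strand half-open intervals on the query genome.
    """
    mapped = 0
    segments: list[tuple[int, int]] = []
    for t0, q0, size in chain.block_coords():
        lo = max(iv.start, t0)
        hi = min(iv.end, t0 + size)
        if lo >= hi:
            continue
        mapped += hi - lo
        q_lo = q0 + (lo - t0)
        q_hi = q0 + (hi - t0)
        if chain.q_strand == "-":
            # reversed-strand coords [q_lo, q_hi) -> forward [q_size-q_hi, q_size-q_lo)
            segments.append((chain.q_size - q_hi, chain.q_size - q_lo))
        else:
            segments.append((q_lo, q_hi))
    return mapped, segments


def _compose_strand(strand: str, q_strand: str) -> str:
    if strand == ".":
        return "."
    if q_strand == "-":
        return "-" if strand == "+" else "+"
    return strand


def lift_interval(
    iv: GenomeInterval,
    chains: ChainIndex,
    min_match: float = 0.95,
    keep_blocks: bool = False,
) -> LiftResult:
    """Lift one interval through the best-scoring overlapping chain.

    The mapped interval is the forward-strand hull of the destination
    positions of the mapped bases; the output strand composes the interval
    strand with the chain's query strand. Status is ``mapped`` when a single
    chain carries >= *min_match* of the bases, ``ambiguous`` when two do,
    ``partial`` when some but too few map, ``unmapped`` otherwise.
    """
    candidates = chains.overlapping(iv.chrom, iv.start, iv.end)
    if not candidates:
        return LiftResult(status="unmapped")
    length = len(iv)
    results = []
    for c in sorted(candidates, key=lambda c: -c.score):
        n_mapped, segments = _map_through_chain(iv, c)
        if n_mapped:
            results.append((n_mapped / length, segments, c))
    if not results:
        return LiftResult(status="unmapped")
    frac, segments, chain = max(results, key=lambda r: (r[2].score, r[0]))
    n_reaching = sum(1 for f, _, _ in results if f >= min_match)
    if frac >= min_match and n_reaching > 1:
        return LiftResult(status="ambiguous", match_fraction=frac,
                          chain_id=chain.chain_id)
    out_strand = _compose_strand(iv.strand, chain.q_strand)
    if frac >= min_match:
        dest = GenomeInterval(
            chain.q_name,
            min(s for s, _ in segments),
            max(e for _, e in segments),
            out_strand,
        )
        blocks = (
            [GenomeInterval(chain.q_name, s, e, out_strand) for s, e in sorted(segments)]
            if keep_blocks
            else []
        )
        return LiftResult(
            status="mapped",
            mapped=dest,
            match_fraction=frac,
            chain_id=chain.chain_id,
            blocks=blocks,
        )
    return LiftResult(status="partial", match_fraction=frac, chain_id=chain.chain_id)


def lift_transcript(
    t: TranscriptModel, chains: ChainIndex, min_match: float = 0.95
) -> LiftResult:
    """Lift a transcript's genomic span (exon hull) to the other genome."""
    return lift_interval(t.span, chains, min_match=min_match)


def lift_annotations(
    transcripts: Iterable[TranscriptModel],
    chains: ChainIndex,
    min_match: float = 0.95,
) -> dict[str, LiftResult]:
    return {t.transcript_id: lift_transcript(t, chains, min_match) for t in transcripts}
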