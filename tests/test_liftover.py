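"""Chain parsing and liftOver semantics, checked against a brute-force
per-base mapper."""

import pytest

from lncons.chain_liftover import (
    Chain,
    ChainBlock,
    ChainFormatError,
    ChainIndex,
    invert_chain,
    lift_interval,
    lift_transcript,
    read_chain,
    write_chain,
)
from lncons.genomic_io import GenomeInterval

from conftest import tx


def make_chain(blocks, t_start=0, q_start=0, q_strand="+", score=100,
               t_name="chrA1", q_name="chrB1", t_size=10_000, q_size=10_000,
               chain_id="1"):
    t_span = sum(b.size + b.dt for b in blocks)
    q_span = sum(b.size + b.dq for b in blocks)
    return Chain(
        score=score, t_name=t_name, t_size=t_size, t_strand="+",
        t_start=t_start, t_end=t_start + t_span,
        q_name=q_name, q_size=q_size, q_strand=q_strand,
        q_start=q_start, q_end=q_start + q_span,
        blocks=list(blocks), chain_id=chain_id,
    )


def brute_force_lift(iv, chains, min_match=0.95):
    """Independent per-base mapper used as the oracle."""
    per_chain = []
    for c in chains:
        if c.t_name != iv.chrom:
            continue
        dest = []
        for t0, q0, size in c.block_coords():
            for pos in range(max(iv.start, t0), min(iv.end, t0 + size)):
                q = q0 + (pos - t0)
                if c.q_strand == "-":
                    q = c.q_size - 1 - q
                dest.append(q)
        if dest:
            per_chain.append((len(dest) / len(iv), dest, c))
    if not per_chain:
        return "unmapped", None, 0.0
    frac, dest, chain = max(per_chain, key=lambda r: (r[2].score, r[0]))
    n_reach = sum(1 for f, _, _ in per_chain if f >= min_match)
    if frac >= min_match and n_reach > 1:
        return "ambiguous", None, frac
    if frac >= min_match:
        return "mapped", (chain.q_name, min(dest), max(dest) + 1), frac
    return "partial", None, frac


class TestReadChain:
    def test_single_block_chain(self, tmp_path):
        path = tmp_path / "a.chain"
        path.write_text(
            "chain 100 chrA 1000 + 0 1000 chrB 1000 + 0 1000 1\n1000\n"
        )
        chains = read_chain(path)
        assert len(chains) == 1
        assert chains[0].blocks == [ChainBlock(1000, 0, 0)]

    def test_block_sum_mismatch_names_chain(self, tmp_path):
        path = tmp_path / "bad.chain"
        path.write_text(
            "chain 100 chrA 1000 + 0 1000 chrB 1000 + 0 1000 7\n900\n"
        )
        with pytest.raises(ChainFormatError, match="7"):
            read_chain(path)

    def test_two_chains_blank_separated(self, tmp_path):
        path = tmp_path / "two.chain"
        path.write_text(
            "chain 10 chrA 1000 + 0 100 chrB 1000 + 0 100 1\n100\n\n"
            "chain 20 chrA 1000 + 200 320 chrB 1000 - 0 120 2\n"
            "50\t10\t10\n60\n\n"
        )
        chains = read_chain(path)
        assert [c.chain_id for c in chains] == ["1", "2"]
        assert chains[1].blocks[0] == ChainBlock(50, 10, 10)

    def test_write_read_round_trip(self, tmp_path):
        chains = [
            make_chain([ChainBlock(50, 10, 20), ChainBlock(40, 0, 0)],
                       t_start=5, q_start=7, q_strand="-"),
        ]
        path = tmp_path / "rt.chain"
        write_chain(chains, path)
        back = read_chain(path)
        assert back[0].blocks == chains[0].blocks
        assert (back[0].q_start, back[0].q_end) == (7, 7 + 110)


class TestLiftInterval:
    def test_identity_chain(self):
        chains = ChainIndex([make_chain([ChainBlock(10_000, 0, 0)])])
        res = lift_interval(GenomeInterval("chrA1", 100, 200, "+"), chains)
        assert res.status == "mapped"
        assert (res.mapped.start, res.mapped.end, res.mapped.strand) == (100, 200, "+")
        assert res.match_fraction == 1.0

    def test_minus_strand_chain_flips_coordinates(self):
        # t [0,1000) -> q rev [0,1000) on a 1000-base query chrom
        chains = ChainIndex(
            [make_chain([ChainBlock(1000, 0, 0)], q_strand="-", q_size=1000)]
        )
        res = lift_interval(GenomeInterval("chrA1", 100, 200, "+"), chains)
        assert res.status == "mapped"
        assert (res.mapped.start, res.mapped.end) == (800, 900)
        assert res.mapped.strand == "-"
        assert res.match_fraction == 1.0

    def test_gap_yields_partial(self):
        # blocks t[0,100)->q[0,100), dt=100 dq=0, t[200,300)->q[100,200)
        chains = ChainIndex(
            [make_chain([ChainBlock(100, 100, 0), ChainBlock(100, 0, 0)])]
        )
        res = lift_interval(GenomeInterval("chrA1", 50, 250, "+"), chains)
        assert res.status == "partial"
        assert res.match_fraction == pytest.approx(0.5)
        assert res.mapped is None

    def test_no_chain_is_unmapped_not_error(self):
        chains = ChainIndex([make_chain([ChainBlock(100, 0, 0)])])
        res = lift_interval(GenomeInterval("chrZ", 0, 10, "+"), chains)
        assert res.status == "unmapped"

    def test_two_good_chains_are_ambiguous(self):
        c1 = make_chain([ChainBlock(1000, 0, 0)], chain_id="1", score=10)
        c2 = make_chain([ChainBlock(1000, 0, 0)], q_start=5000, chain_id="2",
                        score=20)
        res = lift_interval(GenomeInterval("chrA1", 10, 20, "+"),
                            ChainIndex([c1, c2]))
        assert res.status == "ambiguous"

    def test_brute_force_oracle_on_random_chains(self, rng):
        chains = []
        for i in range(8):
            blocks = []
            n = int(rng.integers(1, 4))
            for j in range(n):
                last = j == n - 1
                blocks.append(
                    ChainBlock(
                        int(rng.integers(20, 200)),
                        0 if last else int(rng.integers(0, 80)),
                        0 if last else int(rng.integers(0, 80)),
                    )
                )
            chains.append(
                make_chain(
                    blocks,
                    t_start=int(rng.integers(0, 3000)),
                    q_start=int(rng.integers(0, 3000)),
                    q_strand="-" if rng.random() < 0.5 else "+",
                    score=int(rng.integers(1, 1000)),
                    chain_id=str(i),
                )
            )
        index = ChainIndex(chains)
        for _ in range(300):
            start = int(rng.integers(0, 4000))
            iv = GenomeInterval("chrA1", start, start + int(rng.integers(1, 300)), "+")
            res = lift_interval(iv, index)
            status, mapped, frac = brute_force_lift(iv, chains)
            assert res.status == status
            assert res.match_fraction == pytest.approx(frac, abs=1e-12)
            if status == "mapped":
                assert (res.mapped.chrom, res.mapped.start, res.mapped.end) == mapped

    def test_monotonic_within_plus_chain(self):
        chains = ChainIndex(
            [make_chain([ChainBlock(300, 50, 120), ChainBlock(400, 0, 0)])]
        )
        prev_end = None
        for s in range(0, 700, 60):
            res = lift_interval(GenomeInterval("chrA1", s, s + 40, "+"), chains,
                                min_match=0.99)
            if res.status != "mapped":
                continue
            if prev_end is not None:
                assert res.mapped.start >= prev_end
            prev_end = res.mapped.end


class TestInvertChain:
    @pytest.mark.parametrize("q_strand", ["+", "-"])
    def test_round_trip_restores_interval(self, q_strand, rng):
        for _ in range(100):
            blocks = []
            n = int(rng.integers(1, 4))
            for j in range(n):
                last = j == n - 1
                blocks.append(
                    ChainBlock(int(rng.integers(30, 200)),
                               0 if last else int(rng.integers(0, 50)),
                               0 if last else int(rng.integers(0, 50)))
                )
            chain = make_chain(blocks, t_start=int(rng.integers(0, 2000)),
                               q_start=int(rng.integers(0, 2000)),
                               q_strand=q_strand)
            forward = ChainIndex([chain])
            backward = ChainIndex([invert_chain(chain)])
            # pick an interval fully inside one aligned block
            t0, _, size = list(chain.block_coords())[0]
            iv = GenomeInterval(chain.t_name, t0 + 1, t0 + max(2, size - 1), "+")
            out = lift_interval(iv, forward)
            assert out.status == "mapped"
            back = lift_interval(out.mapped, backward)
            assert back.status == "mapped"
            assert (back.mapped.start, back.mapped.end) == (iv.start, iv.end)
            assert back.mapped.strand == "+"


def test_lift_transcript_uses_span():
    chains = ChainIndex([make_chain([ChainBlock(10_000, 0, 0)])])
    t = tx("t1", chrom="chrA1", strand="-", exons=[(100, 200), (400, 500)])
    res = lift_transcript(t, chains)
    assert res.status == "mapped"
    assert (res.mapped.start, res.mapped.end) == (100, 500)
    assert res.mapped.strand == "-"  # '+' chain keeps the strand
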