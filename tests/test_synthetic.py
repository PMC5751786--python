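"""Contracts and planted-structure checks of the synthetic study generator."""

import numpy as np
import pytest

from lncons.conservation_score import ScoreTrack, score_transcripts
from lncons.synthetic_data import (
    SyntheticConfig,
    SyntheticTruth,
    generate_conservation_track,
    generate_expression,
    generate_genomes,
    generate_go,
    generate_temporal,
)
from lncons.temporal import classify_trends


def small_config(**kwargs):
    defaults = dict(seed=11, n_pcg=60, n_lncrna=20, n_conserved_lnc=10,
                    n_modules=2, module_size=20, n_module_lnc=4,
                    n_monotone_up=3, n_monotone_down=3, n_samples=30,
                    n_go_terms=20)
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_counts_constraints(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_conserved_lnc=50, n_lncrna=40)
        with pytest.raises(ValueError):
            SyntheticConfig(n_bidirectional=30, n_conserved_lnc=20)
        with pytest.raises(ValueError):
            SyntheticConfig(n_monotone_up=15, n_monotone_down=15,
                            n_conserved_lnc=20)

    def test_impossible_fold_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(go_background_rate=0.2,
                            enriched_terms=(("T", 0, 10.0),))

    def test_too_few_samples_rejected(self):
        cfg = small_config()
        ann_a, _, _, truth = generate_genomes(cfg)
        cfg.n_samples = 2
        with pytest.raises(ValueError):
            generate_expression(cfg, ann_a, truth)


class TestGenomes:
    def test_planted_counts(self):
        cfg = small_config()
        ann_a, ann_b, chains, truth = generate_genomes(cfg)
        assert len(truth.conserved_pairs) == cfg.n_conserved_lnc
        assert len(chains) == cfg.n_conserved_lnc
        assert len(truth.bidirectional_pairs_a) == cfg.n_bidirectional
        assert sum(1 for t in ann_a if t.biotype == "lncRNA") == cfg.n_lncrna
        assert sum(1 for t in ann_a if t.biotype == "protein_coding") == cfg.n_pcg
        for a_id, b_id in truth.conserved_pairs:
            assert a_id in ann_a and b_id in ann_b

    def test_bidirectional_distances_as_configured(self):
        cfg = small_config(n_bidirectional=3,
                           bidirectional_distances=(500, 2000, 2001))
        _, _, _, truth = generate_genomes(cfg)
        assert [d for _, _, d in truth.bidirectional_pairs_a] == [500, 2000, 2001]

    def test_same_seed_byte_identical(self, tmp_path):
        from lncons.genomic_io import write_gtf
        from lncons.chain_liftover import write_chain

        for run in ("x", "y"):
            ann_a, _, chains, _ = generate_genomes(small_config())
            write_gtf(ann_a, tmp_path / f"{run}.gtf")
            write_chain(chains, tmp_path / f"{run}.chain")
        assert (tmp_path / "x.gtf").read_bytes() == (tmp_path / "y.gtf").read_bytes()
        assert (tmp_path / "x.chain").read_bytes() == (tmp_path / "y.chain").read_bytes()

    def test_truth_json_round_trip(self, tmp_path):
        _, _, _, truth = generate_genomes(small_config())
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.conserved_pairs == truth.conserved_pairs
        assert back.module_assignment == truth.module_assignment


class TestExpression:
    def test_within_module_correlation_near_target(self):
        cfg = SyntheticConfig(seed=0, within_module_cor=0.9, noise_sd=0.1,
                              n_samples=50)
        ann_a, _, _, truth = generate_genomes(cfg)
        em = generate_expression(cfg, ann_a, truth)
        members = [g for g, m in truth.module_assignment.items() if m == "P1"]
        cors = np.corrcoef(em.values.loc[members].to_numpy())
        iu = np.triu_indices(len(members), 1)
        assert 0.8 <= cors[iu].mean() <= 0.95

    def test_zero_target_gives_no_structure(self):
        cfg = SyntheticConfig(seed=0, within_module_cor=0.0, n_samples=100)
        ann_a, _, _, truth = generate_genomes(cfg)
        em = generate_expression(cfg, ann_a, truth)
        genes = [g for g in truth.module_assignment][:60]
        cors = np.corrcoef(em.values.loc[genes].to_numpy())
        iu = np.triu_indices(len(genes), 1)
        assert np.abs(cors[iu]).mean() < 0.2

    def test_values_non_negative(self):
        cfg = small_config()
        ann_a, _, _, truth = generate_genomes(cfg)
        em = generate_expression(cfg, ann_a, truth)
        assert (em.values.to_numpy() >= 0).all()


class TestTemporal:
    def test_noiseless_recovery_is_exact(self):
        cfg = small_config(noise_sd=0.0)
        _, _, _, truth = generate_genomes(cfg)
        em = generate_temporal(cfg, truth)
        calls = {c.transcript_id: c.trend for c in classify_trends(em)}
        assert calls == truth.trend_labels

    def test_planted_counts(self):
        cfg = small_config()
        _, _, _, truth = generate_genomes(cfg)
        assert sum(1 for v in truth.trend_labels.values() if v == "up") == 3
        assert sum(1 for v in truth.trend_labels.values() if v == "down") == 3

    def test_up_gene_stage_means_strictly_increase(self):
        cfg = small_config(noise_sd=0.0)
        _, _, _, truth = generate_genomes(cfg)
        em = generate_temporal(cfg, truth)
        up = next(t for t, v in truth.trend_labels.items() if v == "up")
        by_stage = em.stages()
        means = [em.values.loc[up, by_stage[s]].mean() for s in cfg.stages]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_noise_at_tenth_of_margin_recalls_planted(self):
        hits = total = 0
        for seed in range(10):
            cfg = small_config(seed=seed, noise_sd=0.1, temporal_step=1.0)
            _, _, _, truth = generate_genomes(cfg)
            em = generate_temporal(cfg, truth)
            calls = {c.transcript_id: c.trend for c in classify_trends(em)}
            planted = {t: v for t, v in truth.trend_labels.items()
                       if v in ("up", "down")}
            hits += sum(calls[t] == v for t, v in planted.items())
            total += len(planted)
        assert hits / total >= 0.9


class TestGo:
    def test_planted_fold_expectation(self):
        # fold 10 on rate 0.05: ~50% membership inside the module vs ~5% out
        inside = outside = n_in = n_out = 0
        for seed in range(10):
            cfg = small_config(seed=seed,
                               enriched_terms=(("T", 0, 10.0),))
            _, _, _, truth = generate_genomes(cfg)
            go = generate_go(cfg, truth)
            members = {g for g, m in truth.module_assignment.items()
                       if m == "P1"} & go.universe
            others = go.universe - members
            inside += len(go.term_genes["T"] & members)
            outside += len(go.term_genes["T"] & others)
            n_in += len(members)
            n_out += len(others)
        assert inside / n_in == pytest.approx(0.5, abs=0.1)
        assert outside / n_out == pytest.approx(0.05, abs=0.03)

    def test_empty_plants_uniform_background(self):
        cfg = small_config(enriched_terms=())
        _, _, _, truth = generate_genomes(cfg)
        go = generate_go(cfg, truth)
        rate = np.mean([len(g) for g in go.term_genes.values()]) / len(go.universe)
        assert rate == pytest.approx(cfg.go_background_rate, abs=0.03)


class TestConservationTrack:
    def test_noise_zero_exact_means(self):
        cfg = small_config(cons_noise_sd=0.0)
        ann_a, _, _, truth = generate_genomes(cfg)
        track = ScoreTrack(generate_conservation_track(cfg, ann_a))
        pcg = [t for t in ann_a if t.biotype == "protein_coding"][:5]
        lnc = [t for t in ann_a if t.biotype == "lncRNA"][:5]
        sp, _ = score_transcripts(pcg, track)
        sl, _ = score_transcripts(lnc, track)
        assert all(v == pytest.approx(0.6) for v in sp.values())
        assert all(v == pytest.approx(0.4) for v in sl.values())

    def test_scores_clipped_to_unit_interval(self):
        cfg = small_config(cons_noise_sd=0.5)
        ann_a, _, _, _ = generate_genomes(cfg)
        data = generate_conservation_track(cfg, ann_a)
        for arr in data.values():
            assert arr["value"].min() >= 0.0 and arr["value"].max() <= 1.0

    def test_group_means_recovered(self):
        cfg = small_config(seed=2)
        ann_a, _, _, _ = generate_genomes(cfg)
        track = ScoreTrack(generate_conservation_track(cfg, ann_a))
        pcg = [t for t in ann_a if t.biotype == "protein_coding"]
        sp, _ = score_transcripts(pcg, track)
        assert np.mean(list(sp.values())) == pytest.approx(0.6, abs=0.02)
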