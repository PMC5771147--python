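"""Forward simulator: reproducibility, drift behaviour, power machinery."""

import numpy as np
import pytest

from finemav.simulator import (
    CaddModel,
    DemographicModel,
    OutlierResult,
    SimulatedWindow,
    SimulationConfig,
    assign_cadd,
    evaluate_outlier_power_fdr,
    evaluate_top_hit_power,
    neutral_cutoff,
    read_windows,
    simulate_scenario,
    simulate_window,
    window_statistic,
    write_windows,
)

# small single-epoch model: three populations exist throughout
TOY_DEMO = DemographicModel(
    sizes=(120, 100, 100), migration=(1e-4, 1e-4, 1e-4), divergence_gens=0
)
TOY_CFG = SimulationConfig(
    n_snps=40, generations=40, sample_size=50, replicates=2, seed=0
)


def make_window(counts, n_chrom=(10, 10, 10), selected=0, cadd=None, s=0.0):
    return SimulatedWindow(
        counts=np.asarray(counts), n_chrom=n_chrom,
        pop_names=("AFR", "EUR", "EAS"), selected_index=selected,
        selected_pop="EUR", s=s, cadd=None if cadd is None else np.asarray(cadd, float),
    )


class TestSimulateWindow:
    def test_seed_determinism(self):
        a = simulate_window(TOY_DEMO, TOY_CFG, 42)
        b = simulate_window(TOY_DEMO, TOY_CFG, 42)
        assert np.array_equal(a.counts, b.counts)
        c = assign_cadd(a, CaddModel(), 7)
        d = assign_cadd(b, CaddModel(), 7)
        assert np.array_equal(c.cadd, d.cadd)
        assert not np.array_equal(a.counts, simulate_window(TOY_DEMO, TOY_CFG, 43).counts)

    def test_two_phase_history_determinism_and_shapes(self):
        demo = DemographicModel(
            sizes=(150, 80, 80), divergence_gens=300, split_gens=150,
            ooa_size=60, migration=(1e-4, 1e-4, 1e-4),
        )
        cfg = SimulationConfig(n_snps=30, generations=200, sample_size=40, seed=0)
        a = simulate_window(demo, cfg, 5)
        b = simulate_window(demo, cfg, 5)
        assert np.array_equal(a.counts, b.counts)
        assert a.counts.shape == (3, 30)
        assert a.n_chrom == (80, 80, 80)
        assert (a.counts <= np.array(a.n_chrom)[:, None]).all()

    def test_selection_onset_after_divergence_rejected(self):
        demo = DemographicModel(
            sizes=(100, 80, 80), divergence_gens=100, split_gens=50, ooa_size=50
        )
        cfg = SimulationConfig(n_snps=10, generations=500, sample_size=20)
        with pytest.raises(ValueError, match="onset predates"):
            simulate_window(demo, cfg, 1)

    def test_neutral_drift_is_unbiased(self):
        """Mean final DAF of a neutrally drifting allele equals its starting
        frequency (Wright-Fisher martingale), within 3 standard errors."""
        demo = DemographicModel(
            sizes=(100, 100, 100), migration=(0.0, 0.0, 0.0), divergence_gens=0
        )
        cfg = SimulationConfig(
            n_snps=5, generations=40, sample_size=50, s=0.0,
            selected_start_daf=0.3, seed=11,
        )
        finals = [
            simulate_window(demo, cfg, seed).daf[:, cfg.selected].mean()
            for seed in range(500)
        ]
        mean, se = np.mean(finals), np.std(finals) / np.sqrt(len(finals))
        assert abs(mean - 0.3) < 3 * se + 1e-3

    def test_strong_selection_sweeps_to_high_frequency(self):
        """With s*t >> 1 the selected allele approaches fixation in the
        selected population (deterministic logistic growth oracle)."""
        demo = DemographicModel(
            sizes=(150, 150, 150), migration=(0.0, 0.0, 0.0), divergence_gens=0
        )
        cfg = SimulationConfig(
            n_snps=20, generations=80, sample_size=80, s=0.25,
            selected_start_daf=0.05, selected_pop="EUR",
        )
        finals = [
            simulate_window(demo, cfg, seed).daf[1, cfg.selected] for seed in range(10)
        ]
        assert np.median(finals) > 0.9
        # selection is population-specific: the others stay low
        others = [simulate_window(demo, cfg, seed).daf[0, cfg.selected] for seed in range(3)]
        assert max(others) < 0.5

    def test_lost_selected_allele_is_not_an_error(self):
        cfg = SimulationConfig(
            n_snps=10, generations=30, sample_size=30, s=0.0,
            selected_start_daf=0.011, seed=3,
        )
        demo = DemographicModel(sizes=(50, 40, 40), migration=(0, 0, 0), divergence_gens=0)
        w = simulate_window(demo, cfg, 12)
        assert w.counts.shape == (3, 10)  # emitted regardless of loss

    def test_rescaling_preserves_power(self):
        """lambda-rescaled runs give top-hit power within 0.1 of unrescaled
        runs on a saturated small pilot."""
        demo = DemographicModel(
            sizes=(400, 400, 400), migration=(1e-4, 1e-4, 1e-4), divergence_gens=0
        )
        powers = []
        for lam in (1.0, 4.0):
            cfg = SimulationConfig(
                n_snps=50, generations=160, sample_size=100, s=0.1,
                selected_start_daf=0.1, replicates=15, seed=21, rescaling=lam,
            )
            ws = simulate_scenario(demo, cfg, cadd_model=CaddModel())
            powers.append(evaluate_top_hit_power(ws, "finemav", 3.5).power)
        assert abs(powers[0] - powers[1]) <= 0.1


class TestCaddAssignment:
    def test_score_ranges_and_determinism(self):
        w = simulate_window(TOY_DEMO, TOY_CFG, 1)
        model = CaddModel()
        scored = assign_cadd(w, model, 99)
        assert scored.cadd.shape == (TOY_CFG.n_snps,)
        assert (scored.cadd >= 0).all()
        lo, hi = model.selected_range
        assert lo <= scored.cadd[w.selected_index] <= hi
        again = assign_cadd(w, model, 99)
        assert np.array_equal(scored.cadd, again.cadd)

    def test_neutral_surrogate_tail_calibration(self):
        rng = np.random.default_rng(0)
        draws = CaddModel().neutral(rng, 200_000)
        assert np.mean(draws > 10) == pytest.approx(0.07, abs=0.01)
        assert draws.max() <= 50

    def test_empirical_model_resamples_pool(self):
        model = CaddModel.from_scores([1.0, 2.0, 3.0])
        rng = np.random.default_rng(0)
        assert set(np.unique(model.neutral(rng, 100))) <= {1.0, 2.0, 3.0}
        with pytest.raises(ValueError):
            CaddModel.from_scores([])


class TestTopHitPower:
    def test_engineered_unique_top_gives_power_one(self):
        counts = np.zeros((3, 5), dtype=int)
        counts[1, 2] = 10  # private fixed in EUR at the selected locus
        counts[:, 0] = (3, 3, 3)
        w = make_window(counts, selected=2)
        for stat in ("delta_daf", "dapxdaf"):
            assert evaluate_top_hit_power([w], stat, 3.5).power == 1.0

    def test_tie_counts_as_failure(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[1, 0] = 10
        counts[1, 1] = 10  # exact duplicate of the selected column
        w = make_window(counts, selected=0)
        assert evaluate_top_hit_power([w], "dapxdaf", 3.5).power == 0.0

    def test_unknown_statistic_errors(self):
        w = make_window(np.ones((3, 4), dtype=int))
        with pytest.raises(ValueError, match="unknown statistic"):
            evaluate_top_hit_power([w], "ihs", 3.5)
        with pytest.raises(ValueError):
            evaluate_top_hit_power([], "dapxdaf", 3.5)

    def test_finemav_requires_scores(self):
        w = make_window(np.ones((3, 4), dtype=int))
        with pytest.raises(ValueError, match="CADD"):
            evaluate_top_hit_power([w], "finemav", 3.5)

    def test_dapxdaf_at_x1_matches_daf_ranking_oracle(self):
        """At x = 1 purity is constant, so the statistic ranks loci exactly
        like the bare derived allele frequency."""
        demo = DemographicModel(
            sizes=(60, 60, 60), migration=(1e-3, 1e-3, 1e-3), divergence_gens=0
        )
        cfg = SimulationConfig(
            n_snps=25, generations=20, sample_size=30, s=0.2,
            selected_start_daf=0.2, replicates=20, seed=33,
        )
        ws = simulate_scenario(demo, cfg)
        expected_hits = 0
        for w in ws:
            daf = w.daf[1]  # selected population
            rest = np.delete(daf, w.selected_index)
            expected_hits += daf[w.selected_index] > rest.max()
        row = evaluate_top_hit_power(ws, "dapxdaf", 1.0)
        assert row.power == pytest.approx(expected_hits / len(ws))


class TestOutlierCutoff:
    def test_constant_pool_returns_constant(self):
        counts = np.tile([[5], [10], [0]], (1, 6))
        w = make_window(counts, n_chrom=(10, 10, 10), cadd=[2.0] * 6)
        value = window_statistic(w, "finemav", 3.5)[0]
        assert neutral_cutoff([w], 3.5, n_boot=5, boot_size=50, seed=0) == pytest.approx(value)

    def test_finds_pool_maximum(self):
        counts = np.zeros((3, 10), dtype=int)
        counts[1] = 10  # fixed in EUR only: DAP = 1, DAF = 1
        w = make_window(counts, cadd=np.arange(1.0, 11.0))
        cut = neutral_cutoff([w], 3.5, n_boot=100, boot_size=1000, seed=1)
        assert cut == pytest.approx(10.0)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            neutral_cutoff([], 3.5)

    def test_power_fdr_counting_oracle(self):
        counts = np.zeros((3, 5), dtype=int)
        counts[1] = 10
        # scores: selected locus 20; neutrals 12, 5, 1, 0.5
        w = make_window(counts, selected=0, cadd=[20.0, 12.0, 5.0, 1.0, 0.5])
        res = evaluate_outlier_power_fdr([w], cutoff=10.0)
        assert res == OutlierResult(power=1.0, fdr=0.5, n_calls=2)
        res = evaluate_outlier_power_fdr([w], cutoff=0.0)
        assert res.power == 1.0 and res.fdr == pytest.approx(4 / 5)

    def test_cutoff_above_everything_flags_zero_denominator(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1] = 10
        w = make_window(counts, cadd=[1.0, 1.0, 1.0])
        res = evaluate_outlier_power_fdr([w], cutoff=99.0)
        assert res.zero_denominator and res.power == 0.0 and res.fdr == 0.0


class TestSerialisation:
    def test_roundtrip(self, tmp_path):
        ws = simulate_scenario(TOY_DEMO, TOY_CFG, seed=3, cadd_model=CaddModel())
        path = write_windows(ws, tmp_path / "w.tsv")
        back = read_windows(path)
        assert len(back) == len(ws)
        for a, b in zip(ws, back):
            assert np.array_equal(a.counts, b.counts)
            assert np.allclose(a.cadd, b.cadd)
            assert a.selected_index == b.selected_index
            assert a.n_chrom == b.n_chrom
            assert a.selected_pop == b.selected_pop

    def test_roundtrip_without_cadd(self, tmp_path):
        ws = simulate_scenario(TOY_DEMO, TOY_CFG, seed=3)
        back = read_windows(write_windows(ws, tmp_path / "w.tsv"))
        assert back[0].cadd is None
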