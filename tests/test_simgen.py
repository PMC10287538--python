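"""Simulation fixtures: parameter draws, neutral coalescent, sweeps, datasets."""

import numpy as np
import pytest
from scipy import stats

import sweepnet as sn
from sweepnet.simgen import (
    ParamDistributions,
    export_dataset,
    import_dataset,
    simulate_batch,
)


@pytest.fixture()
def small_config():
    return sn.SimulationConfig(locus_length=50_000, n_haplotypes=20)


class TestDrawSweepParams:
    def test_point_masses_reproduced_exactly(self):
        cfg = sn.SimulationConfig(
            distributions=ParamDistributions(
                tau=("point", 100.0),
                s=("point", 0.02),
                saf=("point", 0.05),
                eaf=("point", 0.8),
            )
        )
        p = sn.draw_sweep_params(cfg, seed=3)
        assert (p.tau, p.s, p.saf, p.eaf) == (100.0, 0.02, 0.05, 0.8)

    def test_same_seed_identical(self):
        cfg = sn.SimulationConfig()
        assert sn.draw_sweep_params(cfg, 11) == sn.draw_sweep_params(cfg, 11)

    def test_marginals_match_configured_ranges(self):
        cfg = sn.SimulationConfig()
        rng = np.random.default_rng(0)
        draws = [sn.draw_sweep_params(cfg, int(s)) for s in rng.integers(0, 2**31, 10_000)]
        taus = np.array([p.tau for p in draws])
        safs = np.array([p.saf for p in draws])
        eafs = np.array([p.eaf for p in draws])
        log_s = np.log(np.array([p.s for p in draws]))
        tau_hi = 0.125 * 4 * cfg.ne
        assert stats.kstest(taus / tau_hi, "uniform").pvalue > 0.01
        assert stats.kstest(safs / 0.10, "uniform").pvalue > 0.01
        assert stats.kstest((eafs - 0.2) / 0.8, "uniform").pvalue > 0.01
        lo, hi = np.log(0.001), np.log(0.1)
        assert stats.kstest((log_s - lo) / (hi - lo), "uniform").pvalue > 0.01

    def test_inconsistent_ranges_error_after_resampling(self):
        cfg = sn.SimulationConfig(
            distributions=ParamDistributions(saf=("point", 0.9), eaf=("point", 0.5))
        )
        with pytest.raises(ValueError, match="saf < eaf"):
            sn.draw_sweep_params(cfg, 0)


class TestSweepParamsValidation:
    def test_age_beyond_detection_bound_rejected(self):
        with pytest.raises(ValueError, match="0.25"):
            sn.SweepParams(tau=10_001, s=0.01, saf=0.0, eaf=1.0, ne=10_000)

    def test_drift_scale_selection_rejected(self):
        with pytest.raises(ValueError, match="10/"):
            sn.SweepParams(tau=0, s=1e-5, saf=0.0, eaf=1.0, ne=10_000)

    def test_saf_must_be_below_eaf(self):
        with pytest.raises(ValueError, match="saf"):
            sn.SweepParams(tau=0, s=0.01, saf=0.5, eaf=0.4, ne=10_000)


class TestSimulateNeutral:
    def test_deterministic_under_seed(self, small_config):
        assert sn.simulate_neutral(small_config, 5) == sn.simulate_neutral(small_config, 5)
        assert sn.simulate_neutral(small_config, 5) != sn.simulate_neutral(small_config, 6)

    def test_zero_length_locus_rejected(self):
        with pytest.raises(ValueError, match="locus_length"):
            sn.SimulationConfig(locus_length=0)

    def test_watterson_theta_matches_coalescent_expectation(self):
        cfg = sn.SimulationConfig(locus_length=100_000, n_haplotypes=20, ne=10_000)
        theta = 4 * cfg.ne * cfg.mutation_rate * cfg.locus_length
        harmonic = np.sum(1.0 / np.arange(1, cfg.n_haplotypes))
        n_rep = 200
        s_counts = [sn.simulate_neutral(cfg, 500 + i).n_sites for i in range(n_rep)]
        # E[S] = theta * a_n; Var[S] = a_n*theta + b_n*theta^2 (coalescent theory)
        b_n = np.sum(1.0 / np.arange(1, cfg.n_haplotypes) ** 2)
        expected = theta * harmonic
        se = np.sqrt((harmonic * theta + b_n * theta**2) / n_rep)
        assert abs(np.mean(s_counts) - expected) < 3 * se

    def test_scenarios_shift_diversity_in_the_right_direction(self):
        # an ancestrally larger population (decline) carries more variation
        base = dict(locus_length=50_000, n_haplotypes=20)
        eq = [sn.simulate_neutral(sn.SimulationConfig(**base), 700 + i).n_sites for i in range(40)]
        dec = [
            sn.simulate_neutral(sn.SimulationConfig(scenario="decline", **base), 700 + i).n_sites
            for i in range(40)
        ]
        assert np.mean(dec) > np.mean(eq)


class TestSimulateSweep:
    def test_deterministic_under_seed(self, small_config):
        p = sn.SweepParams(tau=0, s=0.05, saf=0.0, eaf=1.0, ne=10_000)
        assert sn.simulate_sweep(small_config, p, 9) == sn.simulate_sweep(small_config, p, 9)

    def test_sweep_reduces_diversity_relative_to_neutral(self, small_config):
        p = sn.SweepParams(tau=0, s=0.05, saf=0.0, eaf=1.0, ne=10_000)
        sweep_s = np.mean([sn.simulate_sweep(small_config, p, i).n_sites for i in range(20)])
        neut_s = np.mean([sn.simulate_neutral(small_config, i).n_sites for i in range(20)])
        assert sweep_s < 0.5 * neut_s

    def test_sweep_signal_in_background_statistics(self, small_config):
        """Mean highfreq near a strong, nearly complete sweep exceeds the
        neutral 95th percentile in most replicates.  (A fully complete
        sweep at this locus size leaves essentially no surviving variation
        at all, so a 90%-complete sweep is the strongest case with
        computable background statistics.)"""
        from sweepnet._engine import LocusEngine

        def mean_highfreq(m):
            if m.n_sites < 2:
                return 0.0
            v = LocusEngine(m).table(10_000)["highfreq"].to_numpy()
            return np.nanmean(v) if np.isfinite(v).any() and v.size else 0.0

        p = sn.SweepParams(tau=0, s=0.03, saf=0.0, eaf=0.9, ne=10_000)
        neut = [mean_highfreq(sn.simulate_neutral(small_config, 100 + i)) for i in range(40)]
        q95 = np.quantile(neut, 0.95)
        n_rep = 25
        hits = sum(
            mean_highfreq(sn.simulate_sweep(small_config, p, 200 + i)) > q95
            for i in range(n_rep)
        )
        assert hits >= 0.6 * n_rep


class TestDatasets:
    def test_import_counts_and_balance(self, tmp_path, small_config):
        neut, _ = simulate_batch(small_config, 4, 1)
        cfg_sweep = sn.SimulationConfig(
            locus_length=50_000, n_haplotypes=20, label="sweep"
        )
        sweep, _ = simulate_batch(cfg_sweep, 4, 2)
        from sweepnet.hapdata import write_ms_file

        write_ms_file(neut, tmp_path / "n.ms")
        write_ms_file(sweep, tmp_path / "s.ms")
        ds = import_dataset(
            [(tmp_path / "n.ms", "neutral"), (tmp_path / "s.ms", "sweep")], 50_000
        )
        assert len(ds) == 8
        assert ds.class_balance == pytest.approx(0.5)

    def test_duplicate_ids_rejected(self, tmp_path, small_config):
        neut, _ = simulate_batch(small_config, 2, 1)
        from sweepnet.hapdata import write_ms_file

        write_ms_file(neut, tmp_path / "n.ms")
        with pytest.raises(ValueError, match="duplicate"):
            import_dataset(
                [(tmp_path / "n.ms", "neutral"), (tmp_path / "n.ms", "sweep")], 50_000
            )

    def test_export_import_round_trip(self, tmp_path, small_config):
        neut, _ = simulate_batch(small_config, 3, 1)
        ds = import_dataset([(_write(tmp_path, neut), "neutral")], 50_000)
        export_dataset(ds, tmp_path / "out")
        again = import_dataset([(tmp_path / "out" / "neutral.ms", "neutral")], 50_000)
        assert sorted(m.n_sites for m in again.matrices) == sorted(
            m.n_sites for m in ds.matrices
        )
        assert all(
            a == b
            for a, b in zip(
                sorted(ds.matrices, key=lambda m: m.n_sites),
                sorted(again.matrices, key=lambda m: m.n_sites),
            )
        )


def _write(tmp_path, matrices):
    from sweepnet.hapdata import write_ms_file

    path = tmp_path / "reps.ms"
    write_ms_file(matrices, path)
    return path
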