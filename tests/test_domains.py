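"""Heterochromatin HMM, binomial mixture EM, per-bin calling, assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, kstest

import loopspread as ls
from loopspread import domains as dm
from loopspread.intervals import IntervalSet
from loopspread.tracks import BinnedTrack

from conftest import reciprocal_hits


def flat_track(n, value, chrom="c", bin_size=40, condition=""):
    return {chrom: BinnedTrack(chrom, bin_size, np.full(n, float(value)), condition)}


class TestHeterochromatinHMM:
    def test_noise_free_block_decoded_exactly(self):
        n = 1000
        inp = flat_track(n, 100, condition="input")
        counts = np.full(n, 100.0)
        counts[300:400] = 400.0
        chip = {"c": BinnedTrack("c", 40, counts, "WT")}
        het = dm.call_heterochromatin_hmm(chip, inp, min_size_bp=0, smooth_bins=1)
        assert len(het) == 1
        assert het.df.iloc[0].start == 300 * 40
        assert het.df.iloc[0].end == 400 * 40

    def test_smoothing_boundary_error_at_most_one_bin(self):
        n = 1000
        inp = flat_track(n, 100, condition="input")
        counts = np.full(n, 100.0)
        counts[300:400] = 400.0
        chip = {"c": BinnedTrack("c", 40, counts, "WT")}
        het = dm.call_heterochromatin_hmm(chip, inp, min_size_bp=0)
        assert len(het) == 1
        assert abs(het.df.iloc[0].start - 12000) <= 40
        assert abs(het.df.iloc[0].end - 16000) <= 40

    def test_constant_track_no_domains(self):
        het = dm.call_heterochromatin_hmm(flat_track(500, 100), flat_track(500, 100))
        assert len(het) == 0

    def test_all_zero_track_raises(self):
        with pytest.raises(dm.DegenerateInputError):
            dm.call_heterochromatin_hmm(flat_track(500, 0), flat_track(500, 100))

    def test_planted_domains_recovered_within_two_bins(self, default_manifest, default_chip):
        het = dm.call_heterochromatin_hmm(default_chip["WT"], default_chip["input"])
        truth = default_manifest.het_domains.df
        for r in truth.itertuples(index=False):
            sub = het.for_chrom(r.chrom)
            err = ((sub["start"] - r.start).abs() + (sub["end"] - r.end).abs()).min()
            assert err <= 2 * 40


class TestBinomialMixture:
    def test_parameter_recovery(self):
        """Planted (0.5, 0.8) mixture at 1e5 bins recovered within ±0.01."""
        rng = np.random.default_rng(11)
        n_bins = 100_000
        n = rng.poisson(200, n_bins).clip(min=1)
        enriched = rng.random(n_bins) < 0.1
        theta = np.where(enriched, 0.8, 0.5)
        t = rng.binomial(n, theta)
        treatment = {"c": BinnedTrack("c", 40, t.astype(float))}
        control = {"c": BinnedTrack("c", 40, (n - t).astype(float))}
        fit = dm.fit_binomial_mixture(treatment, control)
        assert fit.theta_bg == pytest.approx(0.5, abs=0.01)
        assert fit.theta_enr == pytest.approx(0.8, abs=0.01)
        assert fit.converged

    def test_loglik_non_decreasing(self, default_chip):
        fit = dm.fit_binomial_mixture(default_chip["WT"], default_chip["input"])
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()

    def test_single_regime_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        n = rng.poisson(100, 5000).clip(min=1)
        t = rng.binomial(n, 0.5)
        fit = dm.fit_binomial_mixture({"c": BinnedTrack("c", 40, t.astype(float))},
                                      {"c": BinnedTrack("c", 40, (n - t).astype(float))})
        assert abs(fit.theta_enr - fit.theta_bg) < 0.05

    def test_insufficient_data(self):
        with pytest.raises(dm.InsufficientDataError):
            dm.fit_binomial_mixture(flat_track(50, 1), flat_track(50, 1))


class TestEnrichedBins:
    def test_closed_form_tail_probability(self):
        """t=n=20 against θ_bg=0.5 gives p = 0.5^20 before correction."""
        t = np.full(200, 10.0)
        t[0] = 20.0
        c = np.full(200, 10.0)
        c[0] = 0.0
        fit = dm.MixtureFit(0.5, 0.8, (0.9, 0.1), [], True)
        calls = dm.call_enriched_bins({"c": BinnedTrack("c", 40, t)},
                                      {"c": BinnedTrack("c", 40, c)}, fit=fit)
        assert calls.p["c"][0] == pytest.approx(0.5**20, rel=1e-12)

    def test_balanced_bin_not_enriched(self):
        rng = np.random.default_rng(0)
        n = rng.poisson(100, 2000).clip(min=1)
        t = rng.binomial(n, 0.5)
        calls = dm.call_enriched_bins({"c": BinnedTrack("c", 40, t.astype(float))},
                                      {"c": BinnedTrack("c", 40, (n - t).astype(float))})
        assert calls.enriched["c"].sum() <= 0.05 * 2000

    def test_q_values_match_reference_bh(self, default_chip):
        from statsmodels.stats.multitest import multipletests

        calls = dm.call_enriched_bins(default_chip["WT"], default_chip["input"])
        p = np.concatenate([calls.p[c] for c in calls.chroms])
        q = np.concatenate([calls.q[c] for c in calls.chroms])
        t = np.concatenate([default_chip["WT"][c].counts for c in calls.chroms])
        ctrl = np.concatenate([default_chip["input"][c].counts for c in calls.chroms])
        keep = (t + ctrl) > 0
        _, q_ref, _, _ = multipletests(p[keep], method="fdr_bh")
        assert np.allclose(q[keep], q_ref, atol=1e-12)


class TestDifferentialBins:
    def test_identical_tracks_zero_labels(self, default_chip):
        diff = dm.call_differential_bins(default_chip["WT"], default_chip["WT"])
        assert sum(diff.decrease[c].sum() for c in diff.chroms) == 0
        assert sum(diff.increase[c].sum() for c in diff.chroms) == 0

    def test_swap_symmetry(self, default_chip):
        d1 = dm.call_differential_bins(default_chip["WT"], default_chip["KD"])
        d2 = dm.call_differential_bins(default_chip["KD"], default_chip["WT"])
        for c in d1.chroms:
            assert np.array_equal(d1.decrease[c], d2.increase[c])
            assert np.array_equal(d1.increase[c], d2.decrease[c])

    def test_planted_microdomain_bins_labeled_decrease(self, default_manifest, default_chip):
        diff = dm.call_differential_bins(default_chip["WT"], default_chip["KD"])
        micro = default_manifest.microdomains.df
        four_mers = micro[micro["n_mers"] == 4]
        assert len(four_mers)
        frac = []
        for r in four_mers.itertuples(index=False):
            b0, b1 = r.start // 40, r.end // 40
            frac.append(diff.decrease[r.chrom][b0:b1].mean())
        assert np.mean(frac) > 0.9


class TestAssembly:
    def _calls(self, mask, q=None):
        n = len(mask)
        q = np.where(mask, 1e-6, 1.0) if q is None else q
        diff = dm.DifferentialCalls(["c"], 40, {"c": np.asarray(mask, bool)},
                                    {"c": np.zeros(n, bool)}, {"c": q},
                                    {"c": np.ones(n)}, 0, 0.05)
        enr = dm.BinCalls(["c"], 40, {"c": q}, {"c": q},
                          {"c": np.asarray(mask, bool)},
                          dm.MixtureFit(0.5, 0.8, (0.9, 0.1), [], True), 0.05)
        return diff, enr

    def test_gap_zero_splits_runs(self):
        diff, enr = self._calls([1, 1, 0, 1])
        out = dm.assemble_micro_domains(diff, enr, IntervalSet(),
                                        max_gap_bins=0, size_min_bp=0)
        assert [(r.start, r.end) for r in out.df.itertuples(index=False)] == [(0, 80), (120, 160)]

    def test_gap_one_merges_runs(self):
        diff, enr = self._calls([1, 1, 0, 1])
        out = dm.assemble_micro_domains(diff, enr, IntervalSet(),
                                        max_gap_bins=1, size_min_bp=0)
        assert [(r.start, r.end) for r in out.df.itertuples(index=False)] == [(0, 160)]
        assert out.df.iloc[0].n_mers == 1

    def test_size_filter_and_het_exclusion(self):
        mask = np.zeros(200, bool)
        mask[0:60] = True      # 2400 bp -> filtered by size_max
        mask[100:110] = True   # inside het -> excluded
        mask[150:160] = True   # kept
        diff, enr = self._calls(mask)
        het = IntervalSet(pd.DataFrame([("c", 4000, 4400)],
                                       columns=["chrom", "start", "end"]))
        out = dm.assemble_micro_domains(diff, enr, het)
        assert [(r.start, r.end) for r in out.df.itertuples(index=False)] == [(6000, 6400)]
        assert out.df.iloc[0].n_mers == 2

    def test_recovery_on_default_simulation(self):
        """Sensitivity >= 0.9, empirical FDR <= 0.1 over 3 seeds (single-seed stage)."""
        sens, fdr = [], []
        for seed in (21, 22, 23):
            m = ls.build_genome(ls.GenomeSpec(), ls.SimulationParams(seed=seed))
            chip = ls.simulate_chip_tracks(m)
            micro = dm.call_microdomain_pipeline(chip["WT"], chip["KD"], chip["input"])
            truth = m.microdomains.df
            sens.append(reciprocal_hits(truth, micro.df) / len(truth))
            fdr.append(1 - reciprocal_hits(micro.df, truth) / max(len(micro), 1))
        assert min(sens) >= 0.9
        assert max(fdr) <= 0.1


class TestSwapControl:
    def test_identical_tracks_nan_estimate(self, default_chip):
        res = dm.swap_control_fdr(default_chip["WT"], default_chip["WT"],
                                  default_chip["input"], IntervalSet(), n_swaps=2, seed=0)
        assert res.n_real == 0
        assert np.isnan(res.estimate)

    def test_n_swaps_validated(self, default_chip):
        with pytest.raises(ValueError):
            dm.swap_control_fdr(default_chip["WT"], default_chip["KD"],
                                default_chip["input"], IntervalSet(), n_swaps=1)


class TestSummaries:
    def test_mer_distribution_single_mode(self):
        domains = IntervalSet(pd.DataFrame(
            [("c", i * 2000, i * 2000 + 800) for i in range(10)],
            columns=["chrom", "start", "end"]))
        out = dm.mer_size_distribution(domains)
        assert out["mer_counts"].idxmax() == 4
        assert out["fraction_below_2kb"] == 1.0

    def test_mer_distribution_empty_warns(self):
        with pytest.warns(RuntimeWarning):
            out = dm.mer_size_distribution(IntervalSet())
        assert np.isnan(out["fraction_below_2kb"])

    def test_quantify_constant_track(self):
        track = flat_track(100, 7.0)
        iv = IntervalSet(pd.DataFrame([("c", 100, 300), ("c", 1000, 1100)],
                                      columns=["chrom", "start", "end"]))
        vals = dm.quantify_track_in_intervals(track, iv)
        assert np.allclose(vals, vals[0])

    def test_quantify_off_chromosome_raises(self):
        track = flat_track(100, 7.0)
        iv = IntervalSet(pd.DataFrame([("c", 3990, 4200)], columns=["chrom", "start", "end"]))
        with pytest.raises(ValueError, match="off chromosome"):
            dm.quantify_track_in_intervals(track, iv)

    def test_matched_controls_preserve_size_distribution(self, default_manifest):
        gaps = default_manifest.het_domains.complement(default_manifest.spec.chrom_sizes)
        micro = default_manifest.microdomains
        pvals = []
        for seed in range(5):
            ctrl = dm.matched_control_intervals(micro, gaps, seed=seed)
            s1 = (micro.df["end"] - micro.df["start"]).to_numpy()
            s2 = (ctrl.df["end"] - ctrl.df["start"]).to_numpy()
            assert sorted(s1) == sorted(s2)   # exact size matching, one control each
            pvals.append(kstest(s1, s2).pvalue)
        assert min(pvals) > 0.01

    def test_planted_density_ratio(self, default_manifest, default_chip):
        micro = default_manifest.microdomains
        gaps = default_manifest.het_domains.complement(default_manifest.spec.chrom_sizes)
        ctrl = dm.matched_control_intervals(micro, gaps, seed=0)
        d_micro = dm.quantify_track_in_intervals(default_chip["WT"], micro)
        d_ctrl = dm.quantify_track_in_intervals(default_chip["WT"], ctrl)
        assert d_micro.mean() / d_ctrl.mean() == pytest.approx(3.0, rel=0.1)
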