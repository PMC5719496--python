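import numpy as np
import pytest
from hypothesis import given, strategies as st

from lipidims import (PeakList, ProfileSpectrum, aggregate_replicates,
                      generate_profile_spectrum, generate_study, pick_peaks,
                      tic_normalize)

from conftest import small_config


def gaussian_trace(centers_heights, sigma=0.05, lo=600.0, hi=700.0, step=0.01,
                   baseline=5.0, noise_sd=0.0, seed=0):
    grid = np.arange(lo, hi, step)
    y = np.full(grid.shape, baseline)
    for c, h in centers_heights:
        y += h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    if noise_sd:
        y = np.clip(y + np.random.default_rng(seed).normal(0, noise_sd, grid.size), 0, None)
    return ProfileSpectrum(grid, y)


class TestPickPeaks:
    def test_noiseless_gaussian_centroid(self):
        peaks = pick_peaks(gaussian_trace([(700.0 - 50, 100.0)]), mz_min=600, mz_max=700)
        assert len(peaks) == 1
        assert peaks.mz[0] == pytest.approx(650.0, abs=0.01)
        assert peaks.intensity[0] == pytest.approx(100.0, rel=1e-3)

    def test_resolves_isotope_spaced_doublet(self):
        spec = gaussian_trace([(650.0, 100.0), (651.00335, 50.0)])
        # brute-force oracle: strict local maxima of the summed trace
        y = spec.intensity
        apex = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
        assert len(apex) == 2
        peaks = pick_peaks(spec, mz_min=600, mz_max=700)
        assert len(peaks) == 2
        assert peaks.mz[0] == pytest.approx(650.0, abs=0.01)
        assert peaks.mz[1] == pytest.approx(651.00335, abs=0.01)

    def test_pure_noise_false_positive_rate(self):
        # empirical rate frozen from a 100-trace oracle measurement:
        # strict-maximum picking at snr=3 on white per-bin noise admits a
        # small residue (~0.14 peaks/Da), fully suppressed at snr=5; the
        # replicate-consensus stage removes the residue in the pipeline.
        grid = np.arange(600.0, 700.0, 0.01)
        n3 = n5 = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            y = np.clip(5.0 + rng.normal(0, 1.0, grid.size), 0, None)
            spec = ProfileSpectrum(grid, y)
            n3 += len(pick_peaks(spec, snr_threshold=3.0, mz_min=600, mz_max=700))
            n5 += len(pick_peaks(spec, snr_threshold=5.0, mz_min=600, mz_max=700))
        assert n3 / 100 / 100.0 <= 0.25   # peaks per Da, frozen bound
        assert n5 / 100 / 100.0 <= 0.01

    def test_too_short_spectrum_rejected(self):
        spec = ProfileSpectrum(np.array([600.0, 600.01]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="fewer than 3"):
            pick_peaks(spec, mz_min=600, mz_max=700)

    def test_zero_noise_study_recovers_planted_ions_exactly(self):
        for seed in (1, 2, 3):
            cfg = small_config(seed=seed, isotope_prob=0.0)
            study = generate_study(cfg)
            for modality in ("extract", "IMS"):
                planted = np.sort([i.mz for i in study.truth.members(modality)])
                spec = study.spectra[("A8", 0, modality)]
                peaks = pick_peaks(spec, mz_min=600, mz_max=700)
                assert len(peaks) == len(planted)
                np.testing.assert_allclose(peaks.mz, planted, atol=cfg.grid_step)


class TestTicNormalize:
    def test_divides_by_total(self):
        pl = PeakList(np.array([700.0, 800.0, 900.0]), np.array([2.0, 3.0, 5.0]))
        out = tic_normalize(pl)
        assert out.intensity.tolist() == [0.2, 0.3, 0.5]
        assert out.normalized

    def test_single_peak_and_idempotence(self):
        pl = PeakList(np.array([700.0]), np.array([42.0]))
        once = tic_normalize(pl)
        assert once.intensity[0] == 1.0
        twice = tic_normalize(once)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            tic_normalize(PeakList(np.array([700.0]), np.array([0.0])))

    @given(st.lists(st.floats(1e-6, 1e6), min_size=2, max_size=20))
    def test_ratios_preserved(self, intens):
        mz = 600.0 + np.arange(len(intens), dtype=float)
        out = tic_normalize(PeakList(mz, np.asarray(intens)))
        assert abs(out.intensity.sum() - 1.0) <= 1e-9
        before = np.asarray(intens)
        ratio_before = before[0] / before[-1]
        ratio_after = out.intensity[0] / out.intensity[-1]
        assert ratio_after == pytest.approx(ratio_before, rel=1e-12)


def _pl(mz, inten, modality="extract", sid=None):
    pl = PeakList(np.asarray(mz, float), np.asarray(inten, float),
                  sample_id=sid, modality=modality)
    return tic_normalize(pl)


class TestAggregateReplicates:
    def test_identical_lists_give_back_the_list(self):
        reps = [_pl([610.0, 650.0], [1.0, 3.0]) for _ in range(6)]
        cons = aggregate_replicates(reps)
        np.testing.assert_allclose(cons.mz, [610.0, 650.0])
        np.testing.assert_allclose(cons.intensity, [0.25, 0.75])
        assert cons.frequency.tolist() == [1.0, 1.0]

    def test_half_frequency_retained_at_threshold(self):
        reps = [_pl([610.0, 650.0], [1.0, 1.0]) for _ in range(3)]
        reps += [_pl([610.0], [1.0]) for _ in range(3)]
        cons = aggregate_replicates(reps, min_frequency=0.5)
        assert cons.mz.tolist() == [610.0, 650.0]
        assert cons.frequency.tolist() == [1.0, 0.5]
        # absent-as-zero averaging: 3 x 0.5 present + 3 x 0 absent
        assert cons.intensity[1] == pytest.approx(0.25)

    def test_single_linkage_merges_chain_to_mean(self):
        # brute-force single linkage on {700.10, 700.15, 700.20}: all gaps
        # 0.05 <= 0.25, one cluster, consensus at the mean 700.15
        reps = [_pl([700.10], [1.0]), _pl([700.15], [1.0]), _pl([700.20], [1.0])]
        cons = aggregate_replicates(reps, cluster_tol=0.25, min_frequency=0.5)
        assert len(cons) == 1
        assert cons.mz[0] == pytest.approx(700.15)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        reps = [_pl(np.sort(rng.uniform(600, 700, 5)), rng.uniform(1, 10, 5),
                    sid=f"s{k}") for k in range(4)]
        a = aggregate_replicates(reps)
        b = aggregate_replicates(reps[::-1])
        np.testing.assert_allclose(a.mz, b.mz)
        np.testing.assert_allclose(a.intensity, b.intensity)

    def test_mixed_modalities_rejected(self):
        with pytest.raises(ValueError, match="modalit"):
            aggregate_replicates([_pl([600.0], [1.0], "extract"),
                                  _pl([600.0], [1.0], "IMS")])

    def test_unnormalized_inputs_rejected(self):
        raw = PeakList(np.array([600.0]), np.array([2.0]), modality="extract")
        with pytest.raises(ValueError, match="normalized"):
            aggregate_replicates([raw, raw])
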