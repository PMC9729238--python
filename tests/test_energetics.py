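"""Window selection, WHAM PMF estimation and binding free energies."""

import numpy as np
import pytest

from tfx import synth
from tfx.energetics import (DEFAULT_WINDOW_SCHEME, KB_KJ, KJ_PER_KCAL,
                            DeltaG, PMFProfile, PullingTrace, UmbrellaWindow,
                            delta_g, scheme_targets, select_windows,
                            single_window_pmf, wham_pmf)
from tfx.synth import SynthSpec, harmonic_potential, make_umbrella_set


class TestSelectWindows:
    def test_staged_scheme_yields_73_targets_at_stated_spacings(self):
        # linear pull: xi(t) = 0.005 nm/ps
        t = np.arange(0.0, 1718.0, 2.0)
        trace = PullingTrace(t, 0.005 * t)
        chosen = select_windows(trace)
        targets = [c[0] for c in chosen]
        assert len(targets) == 73
        diffs = np.round(np.diff(targets), 10)
        assert np.allclose(diffs[:19], 0.05)
        assert np.allclose(diffs[20:29], 0.1)
        assert np.allclose(diffs[30:], 0.15)
        # chosen xi values within half a sample step of the targets
        for target, time in chosen:
            assert abs(0.005 * time - target) <= 0.005 * 2.0 / 2 + 1e-12

    def test_short_trace_lists_uncovered_targets(self):
        t = np.arange(0.0, 400.0, 2.0)
        trace = PullingTrace(t, 0.005 * t)  # reaches only 2 nm
        with pytest.raises(ValueError, match="does not cover"):
            select_windows(trace)

    def test_ties_resolve_to_earliest_time(self):
        # symmetric triangle: two samples equally close to each target
        times = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        xi = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
        scheme = (((0.0, 1.01), 0.5),)
        chosen = select_windows(PullingTrace(times, xi), scheme)

        # brute-force scan oracle
        for target, time in chosen:
            d = np.abs(xi - target)
            best = np.min(d)
            first = times[np.nonzero(d == best)[0][0]]
            assert time == first


class TestWham:
    def test_recovers_harmonic_curvature_within_10_percent(self):
        spec = SynthSpec(seed=7)
        centres = np.arange(-2.0, 2.01, 0.25)
        windows, _ = make_umbrella_set(spec, potential=harmonic_potential(10.0),
                                       centres=centres, k=100.0, n_samples=500)
        prof = wham_pmf(windows, n_bins=100, n_bootstrap=0)
        mask = np.isfinite(prof.g)
        coef = np.polyfit(prof.xi_grid[mask], prof.g[mask], 2)
        assert 2 * coef[0] == pytest.approx(10.0, rel=0.10)

    def test_flat_potential_gives_flat_pmf(self):
        spec = SynthSpec(seed=3)
        windows, _ = make_umbrella_set(spec, potential=lambda x: 0.0 * x,
                                       centres=np.array([0.0, 0.15]), k=500.0,
                                       n_samples=2000)
        prof = wham_pmf(windows, n_bins=40, n_bootstrap=30)
        # flatness is assessed where the windows actually sample (within
        # 2 sigma of a bias centre) and about the core mean: the min-zero
        # convention pins the reference to the most-negative noise bin
        sigma = np.sqrt(KB_KJ * 310.0 / 500.0)
        core = (np.abs(prof.xi_grid[:, None] - np.array([0.0, 0.15])) <
                2 * sigma).any(axis=1)
        mask = np.isfinite(prof.g) & core
        dev = np.abs(prof.g[mask] - prof.g[mask].mean())
        assert np.all(dev <= np.maximum(2 * prof.se[mask], 0.25))

    def test_single_unbiased_window_equals_log_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0.0, 0.3, 4000)
        w_tiny = UmbrellaWindow(0.0, 1e-9, samples)
        prof = wham_pmf([w_tiny], n_bins=30, n_bootstrap=0)
        direct = single_window_pmf(UmbrellaWindow(0.0, 1e-9, samples), n_bins=30)
        mask = np.isfinite(prof.g) & np.isfinite(direct.g)
        assert np.allclose(prof.g[mask], direct.g[mask], atol=1e-6)

    def test_non_overlapping_windows_raise_with_location(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow(0.0, 1000.0, rng.normal(0.0, 0.05, 200))
        w2 = UmbrellaWindow(5.0, 1000.0, rng.normal(5.0, 0.05, 200))
        with pytest.raises(ValueError, match="non-overlapping"):
            wham_pmf([w1, w2])

    def test_translation_equivariance(self):
        spec = SynthSpec(seed=5)
        centres = np.arange(0.0, 1.01, 0.1)
        pot = harmonic_potential(8.0)
        w_a, _ = make_umbrella_set(spec, potential=pot, centres=centres,
                                   k=200.0, n_samples=300)
        shift = 2.5
        w_b = [UmbrellaWindow(w.xi0 + shift, w.k, w.samples + shift,
                              temperature=w.temperature) for w in w_a]
        pa = wham_pmf(w_a, n_bins=80, n_bootstrap=0)
        pb = wham_pmf(w_b, n_bins=80, n_bootstrap=0)
        mask = np.isfinite(pa.g) & np.isfinite(pb.g)
        assert np.allclose(pb.xi_grid[mask] - pa.xi_grid[mask], shift, atol=1e-9)
        assert np.allclose(pb.g[mask], pa.g[mask], atol=1e-9)

    def test_more_samples_reduce_pmf_error(self):
        pot = harmonic_potential(10.0)
        centres = np.arange(-1.5, 1.51, 0.25)

        def rmse(n_samples, seed):
            spec = SynthSpec(seed=seed)
            windows, _ = make_umbrella_set(spec, potential=pot, centres=centres,
                                           k=100.0, n_samples=n_samples)
            prof = wham_pmf(windows, n_bins=60, n_bootstrap=0)
            mask = np.isfinite(prof.g)
            truth = pot(prof.xi_grid[mask])
            truth -= truth.min()
            return np.sqrt(np.mean((prof.g[mask] - truth) ** 2))

        small = np.mean([rmse(150, s) for s in range(4)])
        large = np.mean([rmse(1500, s) for s in range(4)])
        assert large < small


class TestDeltaG:
    def _profile(self, depth=10.0, noise=0.0, seed=0):
        xi = np.linspace(0.0, 6.0, 121)
        g = depth * (1 - np.exp(-xi ** 2 / (2 * 0.6 ** 2)))
        rng = np.random.default_rng(seed)
        g = g + noise * rng.normal(size=len(xi)) * (xi > 4.2)
        g -= g.min()
        return PMFProfile(xi, g, np.zeros_like(g))

    def test_exact_plateau_minus_minimum(self):
        prof = self._profile(depth=10.0)
        dg = delta_g(prof, plateau_start=4.2)
        assert dg.value == pytest.approx(-10.0, abs=1e-6)
        assert dg.sd == pytest.approx(0.0, abs=1e-9)

    def test_plateau_noise_sd_estimated(self):
        sds = [delta_g(self._profile(noise=0.3, seed=s), 4.2).sd for s in range(100)]
        assert np.mean(sds) == pytest.approx(0.3, rel=0.5)

    def test_plateau_beyond_grid_raises(self):
        prof = self._profile()
        with pytest.raises(ValueError, match="plateau"):
            delta_g(prof, plateau_start=10.0)

    def test_sign_convention_binding_is_negative(self):
        dg = delta_g(self._profile(depth=7.5), 4.2)
        assert dg.value < 0


class TestEndToEnd:
    def test_wham_on_default_binding_well_recovers_depth(self, spec7):
        windows, truth = make_umbrella_set(spec7)
        prof = wham_pmf(windows, n_bootstrap=0)
        dg = delta_g(prof, plateau_start=4.2)
        assert dg.value == pytest.approx(truth["delta_g_bind"], rel=0.15)
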