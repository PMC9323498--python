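"""WHAM solver, binding free energy and bootstrap errors."""

import math

import numpy as np
import pytest

from quenchbind import (
    PMFProfile,
    PMFSpec,
    UmbrellaWindow,
    UmbrellaWindowSet,
    analyze_umbrella,
    binding_delta_g,
    bootstrap_pmf,
    estimate_pmf,
    integrated_autocorrelation_time,
    simulate_umbrella_windows,
    solve_wham,
)
from quenchbind.wham import KB_KJ_MOL

T298 = 298.0
KT = KB_KJ_MOL * T298


# ---------------------------------------------------------------------------
# independent brute-force oracle (scalar loops, no shared code)
# ---------------------------------------------------------------------------

def wham_oracle(counts, bin_centers, centers, springs, temperature,
                n_sweeps=200_000, tol=1e-14):
    """Textbook WHAM fixed point solved with plain Python loops."""
    beta = 1.0 / (0.0083144621 * temperature)
    n_win = len(counts)
    n_bins = len(bin_centers)
    N = [sum(counts[i]) for i in range(n_win)]
    f = [0.0] * n_win
    for _ in range(n_sweeps):
        P = []
        for b in range(n_bins):
            num = sum(counts[i][b] for i in range(n_win))
            den = 0.0
            for i in range(n_win):
                w = 0.5 * springs[i] * (bin_centers[b] - centers[i]) ** 2
                den += N[i] * math.exp(beta * (f[i] - w))
            P.append(num / den if num > 0 else 0.0)
        f_new = []
        for i in range(n_win):
            z = 0.0
            for b in range(n_bins):
                w = 0.5 * springs[i] * (bin_centers[b] - centers[i]) ** 2
                z += P[b] * math.exp(-beta * w)
            f_new.append(-math.log(z) / beta)
        f_new = [fi - f_new[0] for fi in f_new]
        delta = max(abs(a - b) for a, b in zip(f_new, f))
        f = f_new
        if delta < tol:
            break
    total = sum(P)
    pmf = [
        (-math.log(p / total) / beta) if p > 0 else float("nan") for p in P
    ]
    m = min(v for v in pmf if not math.isnan(v))
    return [v - m for v in pmf], f


class TestSolver:
    def test_matches_bruteforce_oracle_on_hand_instance(self):
        """A 3-bin/2-window hand-built histogram instance must agree with
        an independently coded scalar fixed-point solution to 1e-8."""
        counts = np.array([[30.0, 15.0, 5.0], [5.0, 15.0, 30.0]])
        bin_centers = np.array([0.0, 0.5, 1.0])
        centers = np.array([0.0, 1.0])
        springs = np.array([10.0, 10.0])
        pmf, f, _, _ = solve_wham(
            counts, bin_centers, centers, springs, T298, tol=1e-12
        )
        pmf_o, f_o = wham_oracle(
            counts.tolist(), bin_centers.tolist(), centers.tolist(),
            springs.tolist(), T298,
        )
        np.testing.assert_allclose(pmf, pmf_o, atol=1e-8)
        np.testing.assert_allclose(f, f_o, atol=1e-8)

    def test_single_unbiased_window_is_histogram_inversion(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(1.0, 0.2, size=4000)
        ws = UmbrellaWindowSet(
            [UmbrellaWindow(1.0, 0.0, samples)], temperature=T298
        )
        prof = estimate_pmf(ws, n_bins=40)
        counts, _ = np.histogram(samples, bins=prof.bin_edges)
        with np.errstate(divide="ignore"):
            ref = -KT * np.log(counts.astype(float))
        ref = np.where(counts > 0, ref, np.nan)
        ref -= np.nanmin(ref)
        assert prof.n_iter <= 2  # degenerates to direct inversion
        np.testing.assert_allclose(prof.pmf, ref, atol=1e-10)

    def test_harmonic_pmf_recovery(self):
        """11 windows x 5000 samples over U = 25 (xi-1)^2 kJ/mol recover
        the analytic profile with RMSE < 0.5 kJ/mol on supported bins."""
        pmf_true = PMFSpec("harmonic", {"k": 50.0, "x0": 1.0}, domain=(0.0, 2.0))
        ws = simulate_umbrella_windows(
            pmf_true, list(np.linspace(0, 2, 11)), 800.0, 5000, seed=3
        )
        prof = estimate_pmf(ws)
        sup = np.isfinite(prof.pmf)
        resid = prof.pmf[sup] - 0.5 * 50.0 * (prof.xi_grid[sup] - 1.0) ** 2
        resid -= resid.mean()  # PMF is defined up to a constant
        assert math.sqrt(np.mean(resid**2)) < 0.5

    def test_invariant_under_constant_pmf_shift(self):
        # shifting the ground-truth PMF by a constant changes neither the
        # biased densities nor (with the same seed) the samples
        base = PMFSpec("binding_funnel", {"depth": 6.0, "x0": 0.5, "width": 0.1})
        lifted = PMFSpec(
            "binding_funnel",
            {"depth": 6.0, "x0": 0.5, "width": 0.1, "offset": 37.0},
        )
        ws1 = simulate_umbrella_windows(base, [0.4, 0.6], 800.0, 1000, seed=5)
        ws2 = simulate_umbrella_windows(lifted, [0.4, 0.6], 800.0, 1000, seed=5)
        p1 = estimate_pmf(ws1, n_bins=50)
        p2 = estimate_pmf(ws2, n_bins=50)
        np.testing.assert_allclose(p1.pmf, p2.pmf, atol=1e-9)

    def test_non_overlapping_windows_rejected(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow(0.0, 800.0, rng.normal(0.0, 0.05, 500))
        w2 = UmbrellaWindow(2.0, 800.0, rng.normal(2.0, 0.05, 500))
        ws = UmbrellaWindowSet([w1, w2], temperature=T298)
        with pytest.raises(ValueError, match="non-overlapping"):
            estimate_pmf(ws)

    def test_non_convergence_raises(self):
        pmf_true = PMFSpec("harmonic", {"k": 50.0, "x0": 1.0}, domain=(0.0, 2.0))
        ws = simulate_umbrella_windows(
            pmf_true, list(np.linspace(0, 2, 11)), 800.0, 500, seed=3
        )
        with pytest.raises(RuntimeError, match="converge"):
            estimate_pmf(ws, max_iter=3)


class TestBindingDeltaG:
    @staticmethod
    def _profile_from_exact_histograms(spec, centers, k, n_bins=100,
                                       n_per_window=10000.0):
        """Noise-free expected-count histograms for a PMF spec."""
        lo, hi = spec.domain
        edges = np.linspace(lo, hi, n_bins + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        beta = 1.0 / KT
        counts = []
        for c in centers:
            E = spec.energy(mid) + 0.5 * k * (mid - c) ** 2
            dens = np.exp(-beta * (E - E.min()))
            counts.append(n_per_window * dens / dens.sum())
        pmf, f, _, _ = solve_wham(
            np.array(counts), mid, np.array(centers),
            np.full(len(centers), k), T298, tol=1e-10,
        )
        return PMFProfile(xi_grid=mid, pmf=pmf, temperature=T298,
                          bin_edges=edges)

    def test_flat_pmf_gives_zero(self):
        spec = PMFSpec("flat", domain=(0.0, 2.0))
        prof = self._profile_from_exact_histograms(
            spec, list(np.linspace(0, 2, 11)), 800.0
        )
        dg, _ = binding_delta_g(prof)
        assert abs(dg) < 0.02

    def test_well_depth_additivity(self):
        """Deepening the well by delta shifts dG by -delta exactly on
        noise-free histograms."""
        dgs = {}
        for depth in (6.0, 9.0):
            spec = PMFSpec(
                "binding_funnel",
                {"depth": depth, "x0": 0.4, "width": 0.12},
                domain=(0.0, 2.0),
            )
            prof = self._profile_from_exact_histograms(
                spec, list(np.linspace(0, 2, 21)), 800.0
            )
            dgs[depth], _ = binding_delta_g(prof)
        assert dgs[9.0] - dgs[6.0] == pytest.approx(-3.0, abs=0.02)

    def test_plateau_without_support_rejected(self):
        prof = PMFProfile(
            xi_grid=np.linspace(0, 2, 50),
            pmf=np.concatenate([np.zeros(25), np.full(25, np.nan)]),
            temperature=T298,
        )
        with pytest.raises(ValueError, match="plateau"):
            binding_delta_g(prof)


class TestBootstrap:
    def test_seed_reproducibility(self):
        spec = PMFSpec("flat", domain=(0.0, 1.0))
        ws = simulate_umbrella_windows(
            spec, [0.2, 0.5, 0.8], 200.0, 800, seed=6
        )
        b1 = bootstrap_pmf(ws, n_boot=30, seed=42, n_bins=60)
        b2 = bootstrap_pmf(ws, n_boot=30, seed=42, n_bins=60)
        np.testing.assert_array_equal(b1.pmf_se, b2.pmf_se)
        assert b1.delta_g_se == b2.delta_g_se

    def test_block_matches_naive_for_independent_samples(self):
        """With tau ~ 1 the block bootstrap reduces to naive resampling;
        an independently coded naive bootstrap agrees within 20% on the
        median bin SE."""
        spec = PMFSpec("flat", domain=(0.0, 1.0))
        ws = simulate_umbrella_windows(
            spec, [0.25, 0.5, 0.75], 300.0, 2000, seed=8
        )
        boot = bootstrap_pmf(ws, n_boot=80, seed=1, n_bins=50)
        assert np.all(boot.tau < 2.0)
        # naive bootstrap: iid index resampling per window
        prof = estimate_pmf(ws, n_bins=50)
        rng = np.random.default_rng(2)
        reps = []
        centers = np.array([w.center for w in ws.windows])
        springs = np.array([w.k_spring for w in ws.windows])
        for _ in range(80):
            counts = []
            for w in ws.windows:
                idx = rng.integers(0, len(w.samples), len(w.samples))
                c, _ = np.histogram(w.samples[idx], bins=prof.bin_edges)
                counts.append(c)
            pmf_r, _, _, _ = solve_wham(
                np.array(counts, dtype=float), prof.xi_grid, centers,
                springs, T298, f_init=prof.f_windows,
            )
            reps.append(pmf_r)
        naive_se = np.nanstd(np.array(reps), axis=0, ddof=1)
        m_block = np.nanmedian(boot.pmf_se)
        m_naive = np.nanmedian(naive_se)
        assert m_block == pytest.approx(m_naive, rel=0.2)

    def test_se_scales_inverse_sqrt_samples(self):
        spec = PMFSpec("flat", domain=(0.0, 1.0))
        medians = {}
        for n in (800, 3200):
            ws = simulate_umbrella_windows(
                spec, [0.25, 0.5, 0.75], 300.0, n, seed=10
            )
            boot = bootstrap_pmf(ws, n_boot=80, seed=3, n_bins=40)
            medians[n] = float(np.nanmedian(boot.pmf_se))
        ratio = medians[3200] / medians[800]
        assert ratio == pytest.approx(0.5, rel=0.4)  # quadrupling -> 1/2

    def test_tiny_bootstrap_flagged(self):
        spec = PMFSpec("flat", domain=(0.0, 1.0))
        ws = simulate_umbrella_windows(spec, [0.5], 300.0, 500, seed=11)
        boot = bootstrap_pmf(ws, n_boot=2, seed=0, n_bins=30)
        assert boot.delta_g_se is not None or boot.pmf_se is not None
        assert any("low-precision" in w for w in boot.warnings)
        with pytest.raises(ValueError):
            bootstrap_pmf(ws, n_boot=1, seed=0)

    def test_overlong_autocorrelation_rejected(self, monkeypatch):
        # the guard fires when a window's correlation time leaves fewer
        # than two independent blocks in its series
        import quenchbind.wham as wham_mod

        rng = np.random.default_rng(13)
        ws = UmbrellaWindowSet(
            [UmbrellaWindow(0.5, 300.0, rng.normal(0.5, 0.05, 150))],
            temperature=T298,
        )
        monkeypatch.setattr(
            wham_mod, "integrated_autocorrelation_time", lambda x: 80.0
        )
        with pytest.raises(ValueError, match="autocorrelation"):
            bootstrap_pmf(ws, n_boot=10, seed=0, n_bins=30)


class TestAutocorrelationTime:
    def test_white_noise_is_one(self):
        x = np.random.default_rng(3).standard_normal(20000)
        assert integrated_autocorrelation_time(x) == pytest.approx(1.0, abs=0.15)

    def test_ar1_known_time(self):
        # AR(1) with phi: tau = (1+phi)/(1-phi)
        rng = np.random.default_rng(4)
        phi = 0.8
        n = 200_000
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for t in range(1, n):
            x[t] = phi * x[t - 1] + math.sqrt(1 - phi * phi) * eps[t]
        expected = (1 + phi) / (1 - phi)  # 9.0
        assert integrated_autocorrelation_time(x) == pytest.approx(
            expected, rel=0.15
        )
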