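"""1-D weighted histogram analysis method (WHAM) for umbrella sampling.

Umbrella-sampling windows carry samples of a reaction coordinate xi drawn
under harmonic biases w_i(xi) = k_i/2 (xi - xi_i)^2. WHAM removes the
biases self-consistently:

    P(b)  =  sum_i n_i(b)  /  sum_i N_i exp(beta (f_i - w_i(xi_b)))
    f_i   =  -kT ln sum_b P(b) exp(-beta w_i(xi_b))

iterated until the window free energies f_i stop changing. The potential
of mean force is PMF(b) = -kT ln P(b), anchored at min = 0; empty bins
stay masked (NaN), never extrapolated.

Statistical errors come from an autocorrelation-aware block bootstrap:
the integrated autocorrelation time tau of each window's time series is
estimated (Geyer initial-positive-sequence estimator), each window is
resampled in blocks of length ceil(tau), and WHAM is re-solved per
replicate. The binding free energy is read off the converged profile as
PMF at the well minimum minus the mean over the unbound plateau (default:
the last 10% of the coordinate range). No standard-state volume
correction is applied.

Units: kJ/mol and nm throughout; k_B = 0.0083144621 kJ/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "KB_KJ_MOL",
    "UmbrellaWindow",
    "UmbrellaWindowSet",
    "PMFProfile",
    "BootstrapResult",
    "solve_wham",
    "estimate_pmf",
    "binding_delta_g",
    "bootstrap_pmf",
    "analyze_umbrella",
    "integrated_autocorrelation_time",
]

KB_KJ_MOL = 0.0083144621  # kJ / (mol K)

MIN_SAMPLES_PER_WINDOW = 100


@dataclass
class UmbrellaWindow:
    center: float  # nm
    k_spring: float  # kJ mol^-1 nm^-2
    samples: np.ndarray  # xi time series, nm

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.k_spring < 0:
            raise ValueError("k_spring must be non-negative")
        if len(self.samples) < MIN_SAMPLES_PER_WINDOW:
            raise ValueError(
                f"window at {self.center} nm has {len(self.samples)} samples;"
                f" >= {MIN_SAMPLES_PER_WINDOW} required"
            )


@dataclass
class UmbrellaWindowSet:
    windows: list[UmbrellaWindow]
    temperature: float = 298.0  # K
    truth: Any = None  # optional ground-truth PMF (synthetic data only)

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("empty window set")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KJ_MOL * self.temperature)


@dataclass
class PMFProfile:
    """PMF on a bin grid, min-anchored at zero; NaN marks empty bins."""

    xi_grid: np.ndarray  # bin centers, nm
    pmf: np.ndarray  # kJ/mol, min = 0 over supported bins
    pmf_se: np.ndarray | None = None
    delta_g_bind: float | None = None  # kJ/mol
    delta_g_bind_se: float | None = None
    n_bins: int = 0
    n_iter: int = 0
    residual: float = float("nan")
    temperature: float = 298.0
    bin_edges: np.ndarray | None = None
    f_windows: np.ndarray | None = None  # converged window free energies


@dataclass
class BootstrapResult:
    pmf_se: np.ndarray  # per-bin SE, kJ/mol
    delta_g_se: float | None
    tau: np.ndarray  # per-window integrated autocorrelation time, samples
    n_boot: int
    replicate_delta_g: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------

def solve_wham(
    counts: np.ndarray,
    bin_centers: np.ndarray,
    centers: np.ndarray,
    k_springs: np.ndarray,
    temperature: float,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Solve the WHAM self-consistency equations on fixed histograms.

    ``counts`` is (n_windows, n_bins); ``centers``/``k_springs`` give the
    harmonic bias of each window. Returns (pmf, f, n_iter, residual) with
    pmf in kJ/mol (NaN in empty bins, min-anchored at 0) and f the
    converged window free energies (f[0] = 0). Convergence is on
    max|delta f| < tol (kJ/mol).
    """
    counts = np.asarray(counts, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    centers = np.asarray(centers, dtype=float)
    k_springs = np.asarray(k_springs, dtype=float)
    beta = 1.0 / (KB_KJ_MOL * temperature)
    n_win, n_bins = counts.shape
    N = counts.sum(axis=1)  # samples per window
    C = counts.sum(axis=0)  # total counts per bin
    # bias energies w[i, b] and Boltzmann factors
    w = 0.5 * k_springs[:, None] * (bin_centers[None, :] - centers[:, None]) ** 2
    B = np.exp(-beta * w)  # may underflow to 0 far from a window: harmless
    f = np.zeros(n_win) if f_init is None else np.array(f_init, dtype=float)
    occupied = C > 0
    residual = float("inf")
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        a = np.exp(beta * f)
        denom = (N * a) @ B  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(occupied, C / denom, 0.0)
        Z = B @ P  # (n_win,)
        f_new = -np.log(Z) / beta
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3g} kJ/mol > tol {tol:g})"
        )
    a = np.exp(beta * f)
    denom = (N * a) @ B
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(occupied, C / denom, np.nan)
    P /= np.nansum(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmf = -np.log(P) / beta
    pmf = np.where(occupied, pmf, np.nan)
    pmf -= np.nanmin(pmf)
    return pmf, f, n_iter, residual


def _histogram_windows(ws: UmbrellaWindowSet, edges: np.ndarray) -> np.ndarray:
    counts = np.empty((len(ws.windows), len(edges) - 1))
    for i, win in enumerate(ws.windows):
        counts[i], _ = np.histogram(win.samples, bins=edges)
    return counts


def _check_overlap(ws: UmbrellaWindowSet) -> None:
    """Adjacent windows (by center) must have overlapping sample supports."""
    order = np.argsort([w.center for w in ws.windows])
    wins = [ws.windows[i] for i in order]
    gaps = []
    for a, b in zip(wins, wins[1:]):
        if a.samples.max() < b.samples.min() or b.samples.max() < a.samples.min():
            gaps.append((a.center, b.center))
    if gaps:
        desc = ", ".join(f"({x:g} nm, {y:g} nm)" for x, y in gaps)
        raise ValueError(
            "non-overlapping histogram supports between adjacent windows "
            f"at centers: {desc}; add intermediate windows or more sampling"
        )


def estimate_pmf(
    ws: UmbrellaWindowSet,
    n_bins: int = 200,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    xi_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Estimate the PMF from an umbrella window set by WHAM.

    Bins span ``xi_range`` (default: the sampled range). Adjacent windows
    must overlap; non-convergence raises with the final residual.
    """
    _check_overlap(ws)
    if xi_range is None:
        lo = min(w.samples.min() for w in ws.windows)
        hi = max(w.samples.max() for w in ws.windows)
    else:
        lo, hi = xi_range
    if not hi > lo:
        raise ValueError("degenerate coordinate range")
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_centers = 0.5 * (edges[:-1] + edges[1:])
    counts = _histogram_windows(ws, edges)
    centers = np.array([w.center for w in ws.windows])
    k = np.array([w.k_spring for w in ws.windows])
    pmf, f, n_iter, residual = solve_wham(
        counts, bin_centers, centers, k, ws.temperature, tol, max_iter
    )
    return PMFProfile(
        xi_grid=bin_centers,
        pmf=pmf,
        n_bins=n_bins,
        n_iter=n_iter,
        residual=residual,
        temperature=ws.temperature,
        bin_edges=edges,
        f_windows=f,
    )


# ---------------------------------------------------------------------------
# binding free energy
# ---------------------------------------------------------------------------

def binding_delta_g(
    profile: PMFProfile, plateau_fraction: float = 0.1
) -> tuple[float, float | None]:
    """Binding free energy: PMF at the well minimum minus the unbound plateau.

    The plateau is the supported part of the last ``plateau_fraction`` of
    the coordinate range (the dissociated end); it must contain >= 3
    supported bins. Because the profile is min-anchored, the value is
    -mean(plateau) and is negative whenever a well exists. The SE combines
    the bin SEs of the minimum and the plateau mean in quadrature (bins
    treated as independent). Updates ``profile`` in place and returns
    (delta_g, se).
    """
    if not 0 < plateau_fraction < 1:
        raise ValueError("plateau_fraction must be in (0, 1)")
    pmf = profile.pmf
    supported = np.isfinite(pmf)
    if not supported.any():
        raise ValueError("no supported bins in profile")
    xi = profile.xi_grid
    span = xi[-1] - xi[0]
    plateau_mask = supported & (xi >= xi[-1] - plateau_fraction * span)
    if plateau_mask.sum() < 3:
        raise ValueError(
            "fewer than 3 supported bins in the unbound plateau region; "
            "extend sampling toward the dissociated state"
        )
    i_min = int(np.nanargmin(pmf))
    plateau_mean = float(pmf[plateau_mask].mean())
    delta_g = float(pmf[i_min]) - plateau_mean
    se: float | None = None
    if profile.pmf_se is not None:
        se_min = float(profile.pmf_se[i_min])
        se_pl = profile.pmf_se[plateau_mask]
        m = int(plateau_mask.sum())
        se = math.sqrt(se_min**2 + float(np.nansum(se_pl**2)) / m**2)
    profile.delta_g_bind = delta_g
    profile.delta_g_bind_se = se
    return delta_g, se


# ---------------------------------------------------------------------------
# autocorrelation and bootstrap
# ---------------------------------------------------------------------------

def integrated_autocorrelation_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time by Geyer's initial positive sequence.

    tau = -1 + 2 * sum_m Gamma_m over the initial sequence of positive
    paired autocorrelations Gamma_m = rho_{2m} + rho_{2m+1}. Returns at
    least 1 (independent samples).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return 1.0
    xc = x - x.mean()
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(xc, m)
    acov = np.fft.irfft(fx * np.conj(fx), m)[:n].real / n
    if acov[0] <= 0:
        return 1.0
    rho = acov / acov[0]
    tau = -1.0
    for k in range(0, n // 2, 2):
        gamma = rho[k] + (rho[k + 1] if k + 1 < n else 0.0)
        if gamma <= 0:
            break
        tau += 2.0 * gamma
    return max(tau, 1.0)


def _block_resample(rng: np.random.Generator, n: int, block: int) -> np.ndarray:
    """Moving-block bootstrap index vector of length n."""
    if block >= n:
        raise ValueError("block length >= series length")
    n_blocks = -(-n // block)  # ceil
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    idx = (starts[:, None] + np.arange(block)[None, :]).ravel()
    return idx[:n]


def bootstrap_pmf(
    ws: UmbrellaWindowSet,
    n_boot: int = 1000,
    seed: int | None = None,
    n_bins: int = 200,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    plateau_fraction: float = 0.1,
    xi_range: tuple[float, float] | None = None,
    profile: PMFProfile | None = None,
) -> BootstrapResult:
    """Autocorrelation-aware block bootstrap of the WHAM PMF.

    Each window's time series is resampled in contiguous blocks of length
    ceil(tau) (tau = integrated autocorrelation time of that window) and
    WHAM is re-solved per replicate on the point estimate's bin grid;
    resampling never crosses windows, preserving the umbrella design.
    Returns per-bin SEs, the binding-free-energy SE and the per-window
    tau. Fixed seed gives identical SEs.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    warnings: list[str] = []
    if n_boot < 50:
        warnings.append(
            f"n_boot={n_boot} gives low-precision error estimates"
        )
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = estimate_pmf(ws, n_bins=n_bins, tol=tol,
                               max_iter=max_iter, xi_range=xi_range)
    edges = profile.bin_edges
    bin_centers = profile.xi_grid
    centers = np.array([w.center for w in ws.windows])
    k = np.array([w.k_spring for w in ws.windows])
    tau = np.array(
        [integrated_autocorrelation_time(w.samples) for w in ws.windows]
    )
    for w, t in zip(ws.windows, tau):
        if t >= len(w.samples) / 2:
            raise ValueError(
                f"window at {w.center} nm: integrated autocorrelation time "
                f"{t:.0f} >= half the series length ({len(w.samples)}); "
                "insufficient independent data for bootstrap"
            )
    blocks = np.ceil(tau).astype(int)
    pmfs = np.empty((n_boot, len(bin_centers)))
    dgs = np.full(n_boot, np.nan)
    for r in range(n_boot):
        counts = np.empty((len(ws.windows), len(bin_centers)))
        for i, win in enumerate(ws.windows):
            idx = _block_resample(rng, len(win.samples), blocks[i])
            counts[i], _ = np.histogram(win.samples[idx], bins=edges)
        pmf_r, _, _, _ = solve_wham(
            counts, bin_centers, centers, k, ws.temperature,
            tol, max_iter, f_init=profile.f_windows,
        )
        pmfs[r] = pmf_r
        rep = PMFProfile(
            xi_grid=bin_centers, pmf=pmf_r, temperature=ws.temperature,
        )
        try:
            dgs[r], _ = binding_delta_g(rep, plateau_fraction)
        except ValueError:
            pass  # replicate lost plateau support; excluded from the SD
    with np.errstate(invalid="ignore"):
        pmf_se = np.nanstd(pmfs, axis=0, ddof=1)
    good = np.isfinite(dgs)
    dg_se = float(np.std(dgs[good], ddof=1)) if good.sum() >= 2 else None
    result = BootstrapResult(
        pmf_se=pmf_se,
        delta_g_se=dg_se,
        tau=tau,
        n_boot=n_boot,
        replicate_delta_g=dgs,
        warnings=warnings,
    )
    profile.pmf_se = pmf_se
    return result


def analyze_umbrella(
    ws: UmbrellaWindowSet,
    n_bins: int = 200,
    n_boot: int = 1000,
    seed: int | None = None,
    plateau_fraction: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    xi_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Full umbrella-sampling analysis: WHAM + bootstrap + binding dG."""
    profile = estimate_pmf(ws, n_bins=n_bins, tol=tol, max_iter=max_iter,
                           xi_range=xi_range)
    boot = bootstrap_pmf(
        ws, n_boot=n_boot, seed=seed, tol=tol, max_iter=max_iter,
        plateau_fraction=plateau_fraction, profile=profile,
    )
    dg, _ = binding_delta_g(profile, plateau_fraction)
    profile.delta_g_bind = dg
    profile.delta_g_bind_se = boot.delta_g_se
    return profile
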