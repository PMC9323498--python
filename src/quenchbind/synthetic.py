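"""Synthetic data generators with known ground truth.

Every analysis stage in this package has a matching generator here, so
the whole pipeline can be validated round-trip against parameters that
are known exactly:

* fluorescence titrations from the exact 1:1 mass-action binding model
  (with ligand depletion, optional collisional quenching, inner-filter
  attenuation and multiplicative noise), at the study conditions
  (4 uM protein, 0-17 uM ligand in 1 uM steps, 288/298/308 K);
* whole emission spectra as two Gaussian bands (protein tryptophan at
  340 nm / FWHM 28 nm; ligand at 485 nm / FWHM 43 nm);
* far-UV CD spectra of mixed helix/coil content whose 222 nm mean
  residue ellipticity encodes the helix fraction exactly;
* umbrella-sampling windows drawn from the biased Boltzmann density of a
  specified 1-D PMF by grid inverse-CDF sampling (exact stationary
  distribution, optionally AR(1)-correlated in time).

Fixed seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .cd import CHEN_OFFSET, CHEN_SLOPE, CDSpectrum, IL6_N_RESIDUES
from .quench import TitrationSeries, inner_filter_factor
from .thermo import R_GAS
from .wham import (
    KB_KJ_MOL,
    MIN_SAMPLES_PER_WINDOW,
    UmbrellaWindow,
    UmbrellaWindowSet,
)

__all__ = [
    "TitrationGroundTruth",
    "BandParams",
    "EmissionSpectrum",
    "PMFSpec",
    "complex_concentration",
    "simulate_titration",
    "simulate_titration_temperature_set",
    "simulate_emission_spectra",
    "simulate_cd_spectrum",
    "simulate_umbrella_windows",
]

# study conditions: 4 uM protein, ligand 0..17 uM in 1 uM steps
DEFAULT_P0 = 4e-6
DEFAULT_LIGAND_GRID = tuple(i * 1e-6 for i in range(18))
PIPERINE_EPS_EX = 16_500.0  # M^-1 cm^-1 at the 345 nm absorption band


@dataclass
class TitrationGroundTruth:
    """Ground truth for a simulated fluorescence titration.

    ``mode`` selects the quenching model: "static" (ground-state 1:1
    complex, mass action with depletion), "dynamic" (collisional,
    F = F0/(1 + K_D [Q]_free)) or "mixed" (both factors). ``noise_cv`` is
    the coefficient of variation of multiplicative Gaussian noise;
    ``eps_ex``/``eps_em`` are ligand extinction coefficients used to
    build the inner-filter absorbances.
    """

    Ka: float  # M^-1
    P0: float = DEFAULT_P0  # M
    ligand_grid: tuple[float, ...] = DEFAULT_LIGAND_GRID  # M, ascending
    n_stoich: float = 1.0
    mode: str = "static"
    KD_collisional: float = 0.0  # M^-1, dynamic Stern-Volmer constant
    F0: float = 1000.0  # a.u.
    noise_cv: float = 0.0
    eps_ex: float = 0.0  # M^-1 cm^-1
    eps_em: float = 0.0
    path_cm: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.Ka <= 0:
            raise ValueError("Ka must be positive")
        if self.P0 <= 0:
            raise ValueError("P0 must be positive")
        grid = np.asarray(self.ligand_grid, dtype=float)
        if len(grid) == 0 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
            raise ValueError(
                "ligand_grid must be non-empty, non-negative, strictly increasing"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_stoich <= 0:
            raise ValueError("n_stoich must be positive")
        if self.n_stoich != 1.0:
            raise NotImplementedError(
                "only 1:1 stoichiometry (n_stoich=1) is modelled"
            )
        if self.mode not in ("static", "dynamic", "mixed"):
            raise ValueError("mode must be static, dynamic or mixed")
        if self.mode != "static" and self.KD_collisional < 0:
            raise ValueError("KD_collisional must be non-negative")
        if self.F0 <= 0:
            raise ValueError("F0 must be positive")


def complex_concentration(Ka: float, P0: float, Q0: float) -> float:
    """Bound complex [PL] from the exact 1:1 mass-action quadratic.

    Ka = [PL]/([P]_free [Q]_free) with totals P0 and Q0; the numerically
    stable smaller root is returned, 0 <= [PL] <= min(P0, Q0).
    """
    if Q0 == 0.0:
        return 0.0
    b = Ka * (P0 + Q0) + 1.0
    disc = b * b - 4.0 * Ka * Ka * P0 * Q0
    if disc < 0:  # cannot occur for physical inputs; numerical guard
        raise ValueError("negative discriminant in mass-action quadratic")
    x = 2.0 * Ka * P0 * Q0 / (b + math.sqrt(disc))
    if x < -1e-15 or x > min(P0, Q0) * (1 + 1e-12):
        raise ValueError(
            f"non-physical complex concentration {x:g} M for "
            f"P0={P0:g}, Q0={Q0:g}, Ka={Ka:g}"
        )
    return min(max(x, 0.0), min(P0, Q0))


def simulate_titration(
    truth: TitrationGroundTruth, temperature: float = 298.0
) -> TitrationSeries:
    """Simulate one temperature's fluorescence titration.

    Static mode: F_true = F0·(1 - [PL]/P0) with [PL] from the exact
    mass-action quadratic, so (F0-F)/F = Ka·[Q]_free identically.
    Dynamic mode: F_true = F0/(1 + K_D·[Q]_free). Mixed multiplies both.
    The observed intensity then carries inner-filter attenuation
    F_obs = F_true·10^(-(5·A_ex + A_em)/10) with A = eps·[Q]_total·path
    (the exact inverse of the correction applied by the analysis), plus
    multiplicative Gaussian noise. Absorbances are recorded so the
    correction is testable round-trip.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    grid = np.asarray(truth.ligand_grid, dtype=float)
    P0 = truth.P0
    if truth.mode in ("static", "mixed"):
        bound = np.array(
            [complex_concentration(truth.Ka, P0, q) for q in grid]
        )
    else:
        bound = np.zeros_like(grid)
    q_free = grid - bound
    if np.any(q_free < -1e-18):
        raise ValueError("negative free ligand concentration")
    q_free = np.clip(q_free, 0.0, None)
    F_true = np.full_like(grid, truth.F0)
    if truth.mode in ("static", "mixed"):
        F_true = F_true * (1.0 - bound / P0)
    if truth.mode in ("dynamic", "mixed"):
        F_true = F_true / (1.0 + truth.KD_collisional * q_free)
    A_ex = truth.eps_ex * grid * truth.path_cm
    A_em = truth.eps_em * grid * truth.path_cm
    F_obs = F_true / inner_filter_factor(A_ex, A_em)
    if truth.noise_cv > 0:
        rng = np.random.default_rng(truth.seed)
        F_obs = F_obs * (1.0 + truth.noise_cv * rng.standard_normal(len(grid)))
        if np.any(F_obs <= 0):
            raise ValueError(
                "noise drove an intensity non-positive; reduce noise_cv"
            )
    F0_observed = float(F_obs[0]) if grid[0] == 0.0 else float(truth.F0)
    return TitrationSeries(
        temperature=float(temperature),
        P0=P0,
        ligand_total=grid,
        F=F_obs,
        F0=F0_observed,
        A_ex=A_ex,
        A_em=A_em,
        corrected=False,
    )


def simulate_titration_temperature_set(
    dH_kj: float,
    dS_j: float,
    temperatures: list[float],
    base_truth: TitrationGroundTruth,
) -> tuple[list[TitrationSeries], dict[float, float]]:
    """Simulate titrations whose Ka(T) follows the van't Hoff relation.

    Ka(T) = exp(dS/R - dH/(R·T)) with dH in kJ/mol and dS in J/(mol K).
    Returns one series per temperature plus the ground-truth Ka values.
    Seeds derive from ``base_truth.seed`` so temperatures are independent
    but reproducible.
    """
    if len(temperatures) < 1:
        raise ValueError("need at least one temperature")
    if len(set(temperatures)) != len(temperatures):
        raise ValueError("temperatures must be distinct")
    series = []
    ka_true: dict[float, float] = {}
    for i, T in enumerate(sorted(temperatures)):
        if T <= 0:
            raise ValueError("temperatures must be positive (kelvin)")
        Ka = math.exp(dS_j / R_GAS - dH_kj * 1000.0 / (R_GAS * T))
        seed = None if base_truth.seed is None else base_truth.seed + i
        truth_T = replace(base_truth, Ka=Ka, seed=seed)
        series.append(simulate_titration(truth_T, temperature=T))
        ka_true[float(T)] = Ka
    return series, ka_true


# ---------------------------------------------------------------------------
# emission spectra
# ---------------------------------------------------------------------------

@dataclass
class BandParams:
    """Gaussian emission-band parameters for the two-band spectrum model.

    Defaults follow the tryptophan band (340 nm, FWHM 28 nm) and the
    ligand's own emission (485 nm, FWHM 43 nm). ``ligand_amp_per_M``
    scales the ligand band with total ligand concentration; the true
    quantum yield is unknown, so this is a free cosmetic parameter.
    """

    protein_center: float = 340.0
    protein_fwhm: float = 28.0
    ligand_center: float = 485.0
    ligand_fwhm: float = 43.0
    ligand_amp_per_M: float = 2.0e7  # a.u. per M total ligand
    grid: tuple[float, float, float] = (305.0, 570.0, 1.0)  # start, stop, step


@dataclass
class EmissionSpectrum:
    wavelengths: np.ndarray
    intensity: np.ndarray
    ligand_total: float


def _gaussian_band(lam, center, fwhm, amplitude):
    return amplitude * np.exp(-4.0 * math.log(2.0) * (lam - center) ** 2 / fwhm**2)


def simulate_emission_spectra(
    truth: TitrationGroundTruth,
    temperature: float = 298.0,
    band_params: BandParams | None = None,
) -> list[EmissionSpectrum]:
    """Whole emission spectra for every titration point.

    Each spectrum is the sum of a protein Gaussian band whose amplitude
    is the titration intensity at that ligand point and a ligand band
    with amplitude proportional to total ligand. Peak extraction at the
    protein band centre recovers the titration series (the default bands
    are far enough apart that their half-maximum intervals are disjoint).
    """
    bp = band_params or BandParams()
    start, stop, step = bp.grid
    if not (stop > start and step > 0):
        raise ValueError("empty or inverted wavelength grid")
    lam = np.arange(start, stop + step / 2, step)
    for name, c in (("protein", bp.protein_center), ("ligand", bp.ligand_center)):
        if not (lam[0] <= c <= lam[-1]):
            raise ValueError(f"{name} band centre {c} nm outside the grid")
    series = simulate_titration(truth, temperature)
    out = []
    for q, Famp in zip(series.ligand_total, series.F):
        spec = _gaussian_band(lam, bp.protein_center, bp.protein_fwhm, Famp)
        spec = spec + _gaussian_band(
            lam, bp.ligand_center, bp.ligand_fwhm, bp.ligand_amp_per_M * q
        )
        out.append(EmissionSpectrum(lam.copy(), spec, float(q)))
    return out


def extract_band_intensity(
    spectrum: EmissionSpectrum, wavelength: float
) -> float:
    """Intensity at a band centre (linear interpolation on the grid)."""
    return float(
        np.interp(wavelength, spectrum.wavelengths, spectrum.intensity)
    )


# ---------------------------------------------------------------------------
# CD spectra
# ---------------------------------------------------------------------------

def simulate_cd_spectrum(
    helix_percent: float,
    P: float = 4e-6,
    path: float = 0.01,
    n_res: int = IL6_N_RESIDUES,
    noise_mdeg: float = 0.0,
    seed: int | None = None,
    replicate_id: int | str | None = None,
) -> CDSpectrum:
    """Far-UV CD spectrum of a protein with the given helix fraction.

    The helix basis is a double negative Gaussian (n->pi* at 222 nm,
    pi-pi* at 208 nm) normalised so the mixed spectrum's MRE at 222 nm is
    exactly -(2340 + 303·h) — the inversion of the Chen single-wavelength
    formula. The coil basis is constructed to contribute exactly zero at
    222 nm (its shape elsewhere is cosmetic). MRE is converted to
    millidegrees via theta = MRE·10·P·l·n_res and Gaussian noise is added
    in mdeg. Grid: 200-260 nm at 0.1 nm.
    """
    if not 0.0 <= helix_percent <= 100.0:
        raise ValueError("helix_percent must be within [0, 100]")
    if not (P > 0 and path > 0 and n_res > 0):
        raise ValueError("P, path, n_res must be positive")
    lam = np.linspace(200.0, 260.0, 601)
    # helix shape: unit value at 222 nm
    shape = np.exp(-((lam - 222.0) ** 2) / (2 * 7.0**2)) + 0.9 * np.exp(
        -((lam - 208.0) ** 2) / (2 * 5.5**2)
    )
    shape /= shape[220]  # lam[220] == 222.0 exactly
    mre222 = -(CHEN_OFFSET + CHEN_SLOPE / 100.0 * helix_percent)
    helix_component = mre222 * shape
    # coil: negative band near 201 nm, smoothly forced to zero at 222 nm
    coil_amp = -1500.0 * (100.0 - helix_percent) / 100.0
    coil_component = (
        coil_amp
        * np.exp(-((lam - 201.0) ** 2) / (2 * 6.0**2))
        * (1.0 - np.exp(-((lam - 222.0) ** 2) / (2 * 3.0**2)))
    )
    mre = helix_component + coil_component
    theta = mre * (10.0 * P * path * n_res)
    if noise_mdeg > 0:
        rng = np.random.default_rng(seed)
        theta = theta + noise_mdeg * rng.standard_normal(len(lam))
    return CDSpectrum(
        wavelengths=lam,
        theta_mdeg=theta,
        P=P,
        path=path,
        n_res=n_res,
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

@dataclass
class PMFSpec:
    """Analytic 1-D PMF used as ground truth for umbrella sampling.

    Forms: "flat" (U = 0), "harmonic" (U = k/2 (xi - x0)^2 with
    parameters ``k`` kJ/mol/nm^2 and ``x0`` nm) and "binding_funnel"
    (Gaussian well U = -depth·exp(-(xi-x0)^2/(2 width^2)) with a flat
    dissociated tail; parameters ``depth`` kJ/mol >= 0, ``x0`` nm,
    ``width`` nm).
    """

    form: str
    parameters: dict[str, float] = field(default_factory=dict)
    domain: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError("degenerate PMF domain")
        if self.form not in ("flat", "harmonic", "binding_funnel"):
            raise ValueError(f"unknown PMF form {self.form!r}")
        if self.form == "binding_funnel" and self.parameters.get("depth", 0) < 0:
            raise ValueError("well depth must be >= 0")

    def energy(self, xi: np.ndarray | float) -> np.ndarray | float:
        """PMF value (kJ/mol) at coordinate xi (nm).

        All forms accept an optional ``offset`` parameter (kJ/mol); a
        constant shift of the ground truth, which leaves every sampled
        density — and hence the recovered PMF — unchanged.
        """
        xi = np.asarray(xi, dtype=float)
        p = self.parameters
        off = p.get("offset", 0.0)
        if self.form == "flat":
            return np.zeros_like(xi) + off
        if self.form == "harmonic":
            return 0.5 * p["k"] * (xi - p["x0"]) ** 2 + off
        depth, x0, width = p["depth"], p["x0"], p["width"]
        return -depth * np.exp(-((xi - x0) ** 2) / (2.0 * width**2)) + off


GRID_POINTS = 4096  # inverse-CDF grid resolution


def simulate_umbrella_windows(
    pmf: PMFSpec,
    centers: list[float],
    k_spring: float = 800.0,
    n_samples: int = 5000,
    tau_corr: float = 1.0,
    temperature: float = 298.0,
    seed: int | None = None,
) -> UmbrellaWindowSet:
    """Draw umbrella-window samples from the biased Boltzmann density.

    Window i samples density prop. to exp(-beta [U(xi) + k/2 (xi-c_i)^2])
    on a 4096-point grid by inverse-CDF lookup — the exact stationary
    distribution, no dynamics involved. ``tau_corr`` > 1 imposes AR(1)
    time correlation through a Gaussian copula while preserving the
    marginal exactly; the lag-1 coefficient (tau_corr-1)/(tau_corr+1) is
    chosen so the integrated autocorrelation time (1+phi)/(1-phi) of the
    latent series equals tau_corr. The ground-truth PMF is retained on
    the returned set for validation.
    """
    lo, hi = pmf.domain
    for c in centers:
        if not lo <= c <= hi:
            raise ValueError(f"window centre {c} nm outside PMF domain")
    if k_spring < 0:
        raise ValueError("k_spring must be non-negative")
    if n_samples < MIN_SAMPLES_PER_WINDOW:
        raise ValueError(f"n_samples must be >= {MIN_SAMPLES_PER_WINDOW}")
    beta = 1.0 / (KB_KJ_MOL * temperature)
    grid = np.linspace(lo, hi, GRID_POINTS)
    U = np.asarray(pmf.energy(grid), dtype=float)
    rng = np.random.default_rng(seed)
    phi = (tau_corr - 1.0) / (tau_corr + 1.0) if tau_corr > 1.0 else 0.0
    windows = []
    for c in centers:
        E = U + 0.5 * k_spring * (grid - c) ** 2
        E = E - E.min()
        dens = np.exp(-beta * E)
        Z = np.trapezoid(dens, grid)
        if not Z > 0 or not np.isfinite(Z):
            raise ValueError(
                f"biased density numerically zero over the whole domain "
                f"for window at {c} nm"
            )
        cdf = np.concatenate(
            ([0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid)))
        )
        cdf /= cdf[-1]
        if phi > 0.0:
            z = np.empty(n_samples)
            z[0] = rng.standard_normal()
            eps = rng.standard_normal(n_samples - 1)
            for t in range(1, n_samples):
                z[t] = phi * z[t - 1] + math.sqrt(1 - phi * phi) * eps[t - 1]
            u = special.ndtr(z)
        else:
            u = rng.random(n_samples)
        # strictly-increasing CDF segments only, for a stable inverse
        keep = np.concatenate(([True], np.diff(cdf) > 0))
        samples = np.interp(u, cdf[keep], grid[keep])
        windows.append(UmbrellaWindow(center=float(c), k_spring=float(k_spring),
                                      samples=samples))
    return UmbrellaWindowSet(windows=windows, temperature=float(temperature),
                             truth=pmf)
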