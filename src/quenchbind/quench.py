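"""Fluorescence-quenching titration analysis.

Tryptophan fluorescence of a protein (here modelled on interleukin-6, a
single-Trp cytokine) is quenched as a small-molecule ligand is titrated in.
This module implements the three standard linearised analyses:

* inner-filter correction of the observed intensities from the absorbances
  of the sample at the excitation and emission wavelengths,
* the Stern-Volmer regression F0/F = 1 + K_SV [Q], whose temperature
  behaviour distinguishes static (ground-state complex) from dynamic
  (collisional) quenching,
* the double-logarithm binding-equilibrium regression
  log10((F0-F)/F) = n log10 Ka - n log10(1/[Q]_free), which yields the
  association constant Ka and the apparent stoichiometry n, with the free
  ligand corrected for depletion by the bound fraction.

All fits are performed on the linearised coordinates, matching the
published procedure; a non-linear refit on raw intensities is available as
an optional cross-check.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize

__all__ = [
    "TitrationSeries",
    "QuenchFit",
    "BindingFit",
    "MechanismVerdict",
    "correct_inner_filter",
    "stern_volmer_fit",
    "classify_mechanism",
    "double_log_fit",
    "nonlinear_binding_refit",
]

# Fractional fluorescence enhancement above F0 tolerated before a warning
# is recorded (enhancement is unphysical for a pure quencher).
ENHANCEMENT_TOL = 0.05


@dataclass
class TitrationSeries:
    """One temperature's fluorescence titration.

    Concentrations are molar throughout; intensities are in arbitrary
    units. ``A_ex``/``A_em`` are the (dimensionless) absorbances of the
    sample at the excitation and emission wavelengths, used by the
    inner-filter correction.
    """

    temperature: float  # K
    P0: float  # total protein concentration, M
    ligand_total: np.ndarray  # total ligand concentration, M, ascending
    F: np.ndarray  # intensities, a.u.
    F0: float  # intensity at zero ligand, a.u.
    A_ex: np.ndarray | None = None
    A_em: np.ndarray | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.A_ex is not None:
            self.A_ex = np.asarray(self.A_ex, dtype=float)
        if self.A_em is not None:
            self.A_em = np.asarray(self.A_em, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.ligand_total)
        if len(self.F) != n:
            raise ValueError("ligand_total and F must have equal length")
        if np.any(np.diff(self.ligand_total) <= 0):
            raise ValueError("ligand_total must be strictly ascending")
        if self.ligand_total[0] < 0:
            raise ValueError("ligand concentrations must be non-negative")
        if not self.F0 > 0:
            raise ValueError("F0 must be positive")
        if np.any(self.F <= 0):
            raise ValueError("all intensities must be positive")
        if not self.P0 > 0:
            raise ValueError("P0 must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")
        for name, a in (("A_ex", self.A_ex), ("A_em", self.A_em)):
            if a is not None:
                if len(a) != n:
                    raise ValueError(f"{name} length mismatch")
                if np.any(a < 0):
                    raise ValueError(f"{name} must be non-negative")

    def copy(self) -> "TitrationSeries":
        return copy.deepcopy(self)


@dataclass
class QuenchFit:
    """Stern-Volmer regression result: F0/F = intercept + Ksv·[Q]."""

    Ksv: float  # M^-1
    Ksv_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    residuals: np.ndarray
    temperature: float | None = None
    abscissa: str = "total"  # "total" or "free"
    warnings: list[str] = field(default_factory=list)


@dataclass
class BindingFit:
    """Double-log binding regression result (Ka, Hill coefficient n)."""

    Ka: float  # M^-1
    Ka_se: float
    n_hill: float
    n_hill_se: float
    r_squared: float
    x: np.ndarray  # log10(1/[Q]_free)
    y: np.ndarray  # log10((F0-F)/F)
    log10_Ka: float = float("nan")
    log10_Ka_se: float = float("nan")
    temperature: float | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class MechanismVerdict:
    """Quenching-mechanism classification from K_SV(T).

    Static quenching: K_SV flat or decreasing with temperature.
    Dynamic (collisional): K_SV increasing significantly with temperature.
    Mixed: significant increase but at least one non-linear Stern-Volmer
    plot (R^2 below the linearity threshold).
    """

    verdict: str  # static | dynamic | mixed | indeterminate
    slope: float | None  # d K_SV / dT, M^-1 K^-1
    slope_se: float | None
    linearity_ok: dict[float, bool]
    narrative: str


# ---------------------------------------------------------------------------
# inner-filter correction
# ---------------------------------------------------------------------------

def inner_filter_factor(A_ex: np.ndarray, A_em: np.ndarray) -> np.ndarray:
    """Multiplicative correction factor 10^((5·A_ex + A_em)/10).

    The unusual 5:1 weighting of the excitation absorbance reflects the
    10 x 2 mm cuvette geometry used in the source protocol; it is applied
    verbatim. The common symmetric form would be 10^((A_ex+A_em)/2).
    """
    return 10.0 ** ((5.0 * np.asarray(A_ex) + np.asarray(A_em)) / 10.0)


def correct_inner_filter(series: TitrationSeries) -> TitrationSeries:
    """Return a new series with inner-filter-corrected intensities.

    F_corr = F_obs · 10^((5·A_ex + A_em)/10). F0 is recomputed from the
    zero-ligand point when present. The input is left unmodified; applying
    the correction twice is refused.
    """
    if series.corrected:
        raise ValueError("series already inner-filter corrected")
    if series.A_ex is None or series.A_em is None:
        raise ValueError("inner-filter correction requires A_ex and A_em")
    out = series.copy()
    out.F = series.F * inner_filter_factor(series.A_ex, series.A_em)
    if series.ligand_total[0] == 0.0:
        out.F0 = float(out.F[0])
    # with no ligand in the cuvette A_ex = A_em = 0, so F0 is otherwise
    # unaffected by the correction
    out.corrected = True
    return out


# ---------------------------------------------------------------------------
# Stern-Volmer
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray):
    """Plain least squares with slope/intercept SEs, R^2, residuals, cov."""
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    intercept, slope = res.params
    yhat = res.fittedvalues
    resid = y - yhat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot <= np.finfo(float).tiny:
        # constant response fitted exactly by a constant line
        r2 = 1.0 if ss_res <= 1e-24 * max(1.0, float(np.sum(y**2))) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    se_int, se_slope = res.bse
    cov = res.cov_params()
    cov = np.asarray(cov)
    return slope, intercept, float(se_slope), float(se_int), r2, resid, cov


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares (residual-scaled SEs) via statsmodels."""
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    yhat = res.fittedvalues
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, float(se_slope), float(se_int), r2, np.asarray(
        res.cov_params()
    )


def stern_volmer_fit(
    series: TitrationSeries, abscissa: str = "total"
) -> QuenchFit:
    """Fit F0/F = 1 + K_SV·[Q] by ordinary least squares.

    ``abscissa`` selects the quencher axis: "total" (the experimenter's
    known total ligand concentration, the published convention) or "free"
    (total minus the bound estimate fb·P0, with fb = (F0-F)/F0).
    """
    if abscissa not in ("total", "free"):
        raise ValueError("abscissa must be 'total' or 'free'")
    warnings: list[str] = []
    n_nonzero = int(np.sum(series.ligand_total > 0))
    if n_nonzero < 3:
        raise ValueError("Stern-Volmer fit needs >= 3 nonzero-ligand points")
    if not series.corrected and series.A_ex is not None and np.any(series.A_ex > 0):
        warnings.append(
            "series has nonzero absorbances but is not inner-filter corrected"
        )
    if np.any(series.F >= series.F0 * (1.0 + ENHANCEMENT_TOL)):
        warnings.append(
            "fluorescence enhancement above F0 detected (F >= 1.05*F0)"
        )
    q = series.ligand_total
    if abscissa == "free":
        fb = (series.F0 - series.F) / series.F0
        q = q - fb * series.P0
    y = series.F0 / series.F
    slope, intercept, se_slope, se_int, r2, resid, _ = _ols(q, y)
    return QuenchFit(
        Ksv=float(slope),
        Ksv_se=se_slope,
        intercept=float(intercept),
        intercept_se=se_int,
        r_squared=r2,
        residuals=resid,
        temperature=series.temperature,
        abscissa=abscissa,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# mechanism classification
# ---------------------------------------------------------------------------

def _weighted_line(x, y, sigma):
    """Weighted LS with known per-point standard deviations.

    Returns slope, intercept and their SEs from the known-variance
    formulas (no residual rescaling), the physics convention when the
    measurement errors are trusted.
    """
    w = 1.0 / np.asarray(sigma, dtype=float) ** 2
    S = w.sum()
    Sx = (w * x).sum()
    Sy = (w * y).sum()
    Sxx = (w * x * x).sum()
    Sxy = (w * x * y).sum()
    delta = S * Sxx - Sx**2
    slope = (S * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    slope_se = math.sqrt(S / delta)
    intercept_se = math.sqrt(Sxx / delta)
    cov = -Sx / delta
    return slope, intercept, slope_se, intercept_se, cov


# below this relative change of K_SV across the temperature span the trend
# is numerically indistinguishable from flat
FLATNESS_EPS = 1e-9


def classify_mechanism(
    fits: list[tuple[float, QuenchFit]],
    linearity_r2: float = 0.98,
) -> MechanismVerdict:
    """Classify quenching mechanism from K_SV at several temperatures.

    Rule: a positive K_SV(T) slope exceeding 2 standard errors indicates
    collisional (dynamic) quenching — "mixed" if any Stern-Volmer plot is
    additionally non-linear (R^2 < ``linearity_r2``); otherwise static.
    Fewer than two temperatures is indeterminate.
    """
    linearity = {T: f.r_squared >= linearity_r2 for T, f in fits}
    if len(fits) < 2:
        return MechanismVerdict(
            verdict="indeterminate",
            slope=None,
            slope_se=None,
            linearity_ok=linearity,
            narrative="fewer than two temperatures: mechanism indeterminate",
        )
    T = np.array([t for t, _ in fits], dtype=float)
    k = np.array([f.Ksv for _, f in fits], dtype=float)
    se = np.array([f.Ksv_se for _, f in fits], dtype=float)
    scale = float(np.mean(np.abs(k))) or 1.0
    if np.all(np.isfinite(se)) and np.all(se > 1e-12 * scale):
        slope, _, slope_se, _, _ = _weighted_line(T, k, se)
    else:
        slope, _, slope_se, _, r2, _, _ = _ols(T, k)
    rel_change = slope * (T.max() - T.min()) / scale
    significant = (
        slope > 0
        and slope_se > 0
        and slope / slope_se > 2.0
        and abs(rel_change) >= FLATNESS_EPS
    )
    if significant:
        if all(linearity.values()):
            verdict = "dynamic"
            note = (
                "K_SV increases significantly with temperature "
                "(slope/SE > 2): collisional quenching"
            )
        else:
            verdict = "mixed"
            note = (
                "K_SV increases with temperature but at least one "
                "Stern-Volmer plot deviates from linearity: mixed mechanism"
            )
    else:
        verdict = "static"
        note = (
            "K_SV unchanged or decreasing with temperature "
            "(|slope|/SE <= 2): static quenching, ground-state complex"
        )
    return MechanismVerdict(
        verdict=verdict,
        slope=float(slope),
        slope_se=float(slope_se),
        linearity_ok=linearity,
        narrative=note,
    )


# ---------------------------------------------------------------------------
# double-log binding regression
# ---------------------------------------------------------------------------

def double_log_fit(
    series: TitrationSeries, weighting: str = "none"
) -> BindingFit:
    """Fit the binding-equilibrium double-logarithm regression.

    Coordinates: y = log10((F0-F)/F) against x = log10(1/[Q]_free) with
    [Q]_free = [Q]_total - fb·P0 and fb = (F0-F)/F0 (ligand depletion by
    the bound fraction). The line y = c + m·x gives n = -m and
    log10 Ka = c/n; standard errors propagate from the regression
    covariance to first order.

    ``weighting`` selects the regression weights on those coordinates:
    "none" (ordinary least squares, the classical double-log procedure)
    or "fb2" (weights fb^2, the inverse log-coordinate variance under
    constant-CV intensity noise — recommended for noisy data, since
    low-quench points carry strongly amplified log noise; identical to
    OLS on noise-free data).

    Points with F >= F0 carry no quenching information (log of a
    non-positive number) and are excluded with a warning; a non-positive
    free-ligand estimate anywhere is an error.
    """
    if weighting not in ("none", "fb2"):
        raise ValueError("weighting must be 'none' or 'fb2'")
    warnings: list[str] = []
    F0 = series.F0
    keep = series.F < F0
    n_excluded = int(np.sum(~keep & (series.ligand_total > 0)))
    if n_excluded:
        warnings.append(
            f"excluded {n_excluded} nonzero-ligand point(s) with F >= F0"
        )
    keep &= series.ligand_total > 0
    F = series.F[keep]
    Q = series.ligand_total[keep]
    if len(F) < 3:
        raise ValueError("double-log fit needs >= 3 points with F < F0")
    fb = (F0 - F) / F0
    Qf = Q - fb * series.P0
    bad = np.flatnonzero(Qf <= 0)
    if bad.size:
        i = bad[0]
        raise ValueError(
            "non-positive free-ligand estimate at point "
            f"[Q]_total={Q[i]:.3g} M (bound fraction {fb[i]:.3g} x "
            f"P0={series.P0:.3g} M exceeds total ligand)"
        )
    y = np.log10((F0 - F) / F)
    x = np.log10(1.0 / Qf)
    if weighting == "fb2":
        slope, intercept, se_slope, se_int, r2, cov = _wls(x, y, fb**2)
    else:
        slope, intercept, se_slope, se_int, r2, _, cov = _ols(x, y)
    n_hill = -slope
    if n_hill <= 0:
        raise ValueError(
            "double-log slope is non-negative: no resolvable binding"
        )
    log10_Ka = intercept / n_hill
    # L = -c/m; first-order propagation with the (intercept, slope)
    # covariance from the regression
    dL_dc = -1.0 / slope
    dL_dm = intercept / slope**2
    varL = (
        dL_dc**2 * cov[0, 0]
        + dL_dm**2 * cov[1, 1]
        + 2.0 * dL_dc * dL_dm * cov[0, 1]
    )
    log10_Ka_se = math.sqrt(max(varL, 0.0))
    Ka = 10.0**log10_Ka
    Ka_se = Ka * math.log(10.0) * log10_Ka_se
    return BindingFit(
        Ka=float(Ka),
        Ka_se=float(Ka_se),
        n_hill=float(n_hill),
        n_hill_se=float(se_slope),
        r_squared=r2,
        x=x,
        y=y,
        log10_Ka=float(log10_Ka),
        log10_Ka_se=float(log10_Ka_se),
        temperature=series.temperature,
        warnings=warnings,
    )


def nonlinear_binding_refit(
    series: TitrationSeries, start: BindingFit | None = None
) -> tuple[float, float]:
    """Optional cross-check: nonlinear LS of the exact 1:1 model on raw F.

    Fits (Ka, F0) to F = F0·(1 - [PL]/P0) with [PL] from the mass-action
    quadratic. Returns (Ka, Ka_se). This is NOT the published procedure
    (which uses the linearised double-log coordinates); it is offered as
    an independent consistency check only.
    """
    P0 = series.P0
    Q = series.ligand_total
    F = series.F

    def model(q, Ka, F0):
        b = Ka * (P0 + q) + 1.0
        disc = np.sqrt(b * b - 4.0 * Ka * Ka * P0 * q)
        x = 2.0 * Ka * P0 * q / (b + disc)
        return F0 * (1.0 - x / P0)

    Ka0 = start.Ka if start is not None else 1e4
    popt, pcov = optimize.curve_fit(
        model, Q, F, p0=[Ka0, series.F0], maxfev=20000
    )
    return float(popt[0]), float(math.sqrt(max(pcov[0, 0], 0.0)))
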