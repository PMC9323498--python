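"""van't Hoff thermodynamics of protein-ligand association.

ln Ka is regressed on 1/T; the slope gives -dH/R and the intercept dS/R,
and Gibbs free energy follows as dG(T) = dH - T·dS. Energies are reported
in kJ/mol (dS in J/mol/K), with R = 8.314 J/mol/K. A sign rule-table maps
(dH, dS) onto the conventional driving-force interpretation for
protein-ligand complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .quench import _ols, _weighted_line

__all__ = [
    "R_GAS",
    "ThermoParams",
    "ForceInterpretation",
    "vant_hoff_fit",
    "gibbs_free_energy",
    "interpret_forces",
]

R_GAS = 8.314  # J / (mol K)


@dataclass
class ThermoParams:
    """Fitted van't Hoff parameters with propagated uncertainties.

    dH in kJ/mol, dS in J/(mol K); dG_by_T maps temperature (K) to
    (dG kJ/mol, SE kJ/mol or None). With exactly two temperatures the
    regression has zero residual degrees of freedom (unweighted case) and
    standard errors are reported as None.
    """

    dH: float
    dH_se: float | None
    dS: float
    dS_se: float | None
    dG_by_T: dict[float, tuple[float, float | None]] = field(default_factory=dict)
    r_squared: float = float("nan")
    R_const: float = R_GAS
    temperatures: tuple[float, ...] = ()
    # (slope, intercept) covariance of the ln Ka vs 1/T line, J-free units
    _cov: np.ndarray | None = None
    _slope: float = float("nan")
    _intercept: float = float("nan")


@dataclass
class ForceInterpretation:
    driving_forces: str
    endothermic: bool
    spontaneous_by_T: dict[float, bool]
    narrative: str


def vant_hoff_fit(
    ka_by_T: list[tuple[float, float, float | None]]
) -> ThermoParams:
    """Weighted linear regression of ln Ka on 1/T.

    ``ka_by_T`` is a list of (temperature K, Ka M^-1, Ka_se M^-1 or None).
    When all standard errors are supplied and positive the fit is weighted
    by the errors of ln Ka, delta(ln Ka) = Ka_se/Ka, with known-variance
    standard errors; otherwise an ordinary fit with residual-based errors
    is used. dH = -R·slope, dS = R·intercept.
    """
    if len(ka_by_T) < 2:
        raise ValueError("van't Hoff fit needs >= 2 temperatures")
    T = np.array([t for t, _, _ in ka_by_T], dtype=float)
    Ka = np.array([k for _, k, _ in ka_by_T], dtype=float)
    se = np.array(
        [s if s is not None else np.nan for _, _, s in ka_by_T], dtype=float
    )
    if len(np.unique(T)) != len(T):
        raise ValueError("duplicate temperatures in van't Hoff input")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    if np.any(Ka <= 0):
        raise ValueError("association constants must be positive")
    x = 1.0 / T
    y = np.log(Ka)
    weighted = np.all(np.isfinite(se)) and np.all(se > 0)
    if weighted:
        sigma = se / Ka  # delta(ln Ka)
        slope, intercept, slope_se, int_se, cov_si = _weighted_line(x, y, sigma)
        cov = np.array(
            [[slope_se**2, cov_si], [cov_si, int_se**2]], dtype=float
        )
        yhat = intercept + slope * x
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        have_se = True
    else:
        slope, intercept, slope_se, int_se, r2, _, cov_oi = _ols(x, y)
        # _ols returns the (intercept, slope) covariance; reorder
        cov = np.array(
            [
                [cov_oi[1, 1], cov_oi[0, 1]],
                [cov_oi[0, 1], cov_oi[0, 0]],
            ],
            dtype=float,
        )
        have_se = len(T) > 2  # 2 points: zero residual dof
    dH = -R_GAS * slope / 1000.0  # kJ/mol
    dS = R_GAS * intercept  # J/(mol K)
    params = ThermoParams(
        dH=float(dH),
        dH_se=float(R_GAS * slope_se / 1000.0) if have_se else None,
        dS=float(dS),
        dS_se=float(R_GAS * int_se) if have_se else None,
        r_squared=float(r2),
        temperatures=tuple(float(t) for t in T),
        _cov=cov if have_se else None,
        _slope=float(slope),
        _intercept=float(intercept),
    )
    return gibbs_free_energy(params, list(params.temperatures))


def gibbs_free_energy(
    params: ThermoParams, temperatures: list[float]
) -> ThermoParams:
    """Fill dG(T) = dH - T·dS (kJ/mol) with propagated SEs.

    In terms of the fitted line (slope m, intercept b of ln Ka vs 1/T),
    dG(T) = -R·(m + T·b), so its variance follows directly from the
    (m, b) covariance. Requires a fitted ``params``.
    """
    if not np.isfinite(params._slope):
        raise ValueError("params must come from vant_hoff_fit")
    for T in temperatures:
        if T <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        dG = params.dH - T * params.dS / 1000.0  # kJ/mol
        if params._cov is not None:
            c = params._cov
            var = R_GAS**2 * (c[0, 0] + T**2 * c[1, 1] + 2.0 * T * c[0, 1])
            se = math.sqrt(max(var, 0.0)) / 1000.0
        else:
            se = None
        params.dG_by_T[float(T)] = (float(dG), se)
    return params


def interpret_forces(params: ThermoParams) -> ForceInterpretation:
    """Classify the dominant intermolecular forces from the signs of dH, dS.

    Conventional rule table for protein-ligand complexes: dH>0 & dS>0 ->
    hydrophobic/non-specific; dH<0 & dS<0 -> hydrogen bonding / van der
    Waals; dH<0 & dS>0 -> electrostatic. A positive dH flags an
    endothermic complexation; dG < 0 flags spontaneity per temperature.
    """
    dH, dS = params.dH, params.dS
    if dH > 0 and dS > 0:
        forces = "hydrophobic/non-specific"
    elif dH < 0 and dS < 0:
        forces = "hydrogen bond / van der Waals"
    elif dH < 0 and dS > 0:
        forces = "electrostatic"
    else:
        forces = "indeterminate (dH >= 0, dS <= 0: binding enthalpically and entropically disfavoured)"
    spont = {T: dG < 0 for T, (dG, _) in params.dG_by_T.items()}
    endo = dH > 0
    bits = [f"dominant forces: {forces}"]
    bits.append("endothermic complexation" if endo else "exothermic complexation")
    if spont and all(spont.values()):
        bits.append("spontaneous (dG < 0) at all analysed temperatures")
    elif spont:
        non = [f"{T:g} K" for T, ok in spont.items() if not ok]
        bits.append("NOT spontaneous at: " + ", ".join(non))
    return ForceInterpretation(
        driving_forces=forces,
        endothermic=endo,
        spontaneous_by_T=spont,
        narrative="; ".join(bits),
    )
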