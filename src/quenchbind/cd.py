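"""Circular-dichroism alpha-helix content from the 222 nm ellipticity.

The raw ellipticity theta (millidegrees) is converted to mean residue
ellipticity, [theta] = theta / (10·[P]·l·n_res) in deg cm^2 dmol^-1, and
the helix fraction follows from the single-wavelength (222 nm) method of
Chen: % helix = (|MRE_222| - 2340) / 30300 · 100. The formula is applied
to the magnitude of the (negative) 222 nm ellipticity, which is the
convention that reproduces positive helix fractions for helical proteins.

MRE at 222 nm is read as the average over a small symmetric wavelength
window (default +/-0.3 nm) of the digitised spectrum, which suppresses
per-point instrument noise without biasing the broad n->pi* band.
Replicate spectra yield a sample-SD uncertainty.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CDSpectrum",
    "HelixEstimate",
    "HelixChange",
    "CHEN_OFFSET",
    "CHEN_SLOPE",
    "mdeg_to_mre",
    "mre_at",
    "helix_percent",
    "helix_from_spectrum",
    "helix_from_spectra",
    "helix_change",
]

# Chen single-wavelength calibration constants (deg cm^2 dmol^-1):
# |MRE_222| = CHEN_OFFSET + CHEN_SLOPE/100 * (% helix)
CHEN_OFFSET = 2340.0
CHEN_SLOPE = 30300.0

# tolerated overshoot above 100% helix before it is treated as a
# metadata error rather than measurement noise (percentage points)
CLAMP_SLACK = 5.0

IL6_N_RESIDUES = 185  # default residue count (human interleukin-6)


@dataclass
class CDSpectrum:
    """Far-UV CD spectrum with the metadata needed for MRE conversion."""

    wavelengths: np.ndarray  # nm
    theta_mdeg: np.ndarray  # millidegrees
    P: float  # protein concentration, M
    path: float  # optical path, cm
    n_res: int = IL6_N_RESIDUES
    replicate_id: int | str | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.theta_mdeg = np.asarray(self.theta_mdeg, dtype=float)
        if len(self.wavelengths) != len(self.theta_mdeg):
            raise ValueError("wavelengths and theta_mdeg length mismatch")
        if len(self.wavelengths) == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not (self.P > 0 and self.path > 0 and self.n_res > 0):
            raise ValueError("P, path and n_res must be positive")


@dataclass
class HelixEstimate:
    mre222: float  # deg cm^2 dmol^-1 (signed, typically negative)
    helix_percent: float  # 0..100
    se: float | None = None  # from replicates, percentage points
    constants: tuple[float, float] = (CHEN_OFFSET, CHEN_SLOPE)
    clamped: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass
class HelixChange:
    """Helix-content difference between two conditions.

    Reports both the absolute percentage-point difference and the change
    relative to the starting content (in %), each with a quadrature-
    propagated SE when replicate SEs are available.
    """

    delta_points: float
    delta_points_se: float | None
    relative_percent: float
    relative_percent_se: float | None


def mdeg_to_mre(spec: CDSpectrum) -> np.ndarray:
    """Convert millidegree ellipticity to mean residue ellipticity.

    [theta](lambda) = theta(lambda) / (10 · [P] · l · n_res), in
    deg cm^2 dmol^-1, for molar protein concentration [P], path l in cm
    and n_res residues. Buffer-blank subtraction is assumed upstream.
    """
    return spec.theta_mdeg / (10.0 * spec.P * spec.path * spec.n_res)


def mre_at(
    spec: CDSpectrum, wavelength: float = 222.0, window_nm: float = 0.3
) -> float:
    """MRE at a wavelength, averaged over a +/-``window_nm`` window.

    Falls back to linear interpolation when the window contains no grid
    point. The wavelength must lie inside the spectrum's range.
    """
    w = spec.wavelengths
    if not (w[0] <= wavelength <= w[-1]):
        raise ValueError(
            f"wavelength {wavelength} nm outside spectrum range "
            f"[{w[0]}, {w[-1]}] nm"
        )
    mre = mdeg_to_mre(spec)
    sel = np.abs(w - wavelength) <= window_nm + 1e-9
    if np.any(sel):
        return float(mre[sel].mean())
    return float(np.interp(wavelength, w, mre))


def helix_percent(mre222: float) -> HelixEstimate:
    """Chen single-wavelength helix fraction from MRE at 222 nm.

    % helix = (|MRE_222| - 2340) / 30300 · 100. Values slightly outside
    [0, 100] — measurement noise around a fully disordered or fully
    helical protein — are clamped to the boundary with a warning; an
    excess beyond ``slack`` (default 5 points) indicates wrong
    concentration/path metadata and is an error.
    """
    if not math.isfinite(mre222):
        raise ValueError("MRE at 222 nm must be finite")
    h = (abs(mre222) - CHEN_OFFSET) / CHEN_SLOPE * 100.0
    warn: list[str] = []
    clamped = False
    if h > 100.0 + CLAMP_SLACK:
        raise ValueError(
            f"helix content {h:.1f}% > 100%: |MRE222|={abs(mre222):.0f} "
            "exceeds the fully helical limit; check concentration/path "
            "metadata"
        )
    if h < 0:
        warn.append(
            f"|MRE222|={abs(mre222):.0f} below the disordered baseline "
            f"({CHEN_OFFSET:.0f}): helix content clamped to 0"
        )
        _warnings.warn(warn[-1], stacklevel=2)
        h = 0.0
        clamped = True
    elif h > 100.0:
        warn.append(
            f"helix content {h:.1f}% marginally above the fully helical "
            "limit: clamped to 100"
        )
        _warnings.warn(warn[-1], stacklevel=2)
        h = 100.0
        clamped = True
    return HelixEstimate(
        mre222=float(mre222), helix_percent=float(h), clamped=clamped,
        warnings=warn,
    )


def helix_from_spectrum(spec: CDSpectrum, window_nm: float = 0.3) -> HelixEstimate:
    """Helix estimate from a single spectrum (no replicate SE)."""
    return helix_percent(mre_at(spec, 222.0, window_nm=window_nm))


def helix_from_spectra(
    spectra: list[CDSpectrum], window_nm: float = 0.3
) -> HelixEstimate:
    """Helix estimate from replicate spectra.

    The helix fraction is computed per replicate; the estimate is their
    mean and the uncertainty the sample SD over replicates (the spread a
    triplicate protocol reports). A single spectrum yields no SE.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    singles = [helix_from_spectrum(s, window_nm=window_nm) for s in spectra]
    hs = np.array([s.helix_percent for s in singles])
    mres = np.array([s.mre222 for s in singles])
    est = HelixEstimate(
        mre222=float(mres.mean()),
        helix_percent=float(hs.mean()),
        se=float(hs.std(ddof=1)) if len(hs) > 1 else None,
        clamped=any(s.clamped for s in singles),
        warnings=[w for s in singles for w in s.warnings],
    )
    return est


def helix_change(before: HelixEstimate, after: HelixEstimate) -> HelixChange:
    """Helix-content change between two conditions (e.g. apo vs ligand).

    delta_points = after - before (percentage points);
    relative_percent = 100·(after - before)/before. SEs are propagated in
    quadrature (and to first order for the ratio) when both inputs carry
    replicate SEs.
    """
    b, a = before.helix_percent, after.helix_percent
    delta = a - b
    rel = 100.0 * delta / b if b != 0 else float("nan")
    if before.se is not None and after.se is not None:
        delta_se = math.hypot(before.se, after.se)
        if b != 0:
            rel_se = 100.0 * math.hypot(after.se / b, a * before.se / b**2)
        else:
            rel_se = None
    else:
        delta_se = None
        rel_se = None
    return HelixChange(
        delta_points=float(delta),
        delta_points_se=delta_se,
        relative_percent=float(rel),
        relative_percent_se=rel_se,
    )
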