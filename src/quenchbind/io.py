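"""File formats, JSON reporting and the end-to-end pipeline.

Tabular inputs are TSV/CSV with '#key=value' metadata header lines;
results serialise to a JSON report that is a machine-readable twin of the
experimental summary tables (quench/binding fits per temperature,
mechanism verdict, van't Hoff thermodynamics, helix content, PMF).
Concentrations are stored in molar internally; readers accept a
``ligand_units``/``conc_units`` metadata key (default uM for titrations)
and convert at the boundary.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cd import CDSpectrum, helix_change, helix_from_spectra
from .quench import (
    BindingFit,
    MechanismVerdict,
    QuenchFit,
    TitrationSeries,
    classify_mechanism,
    correct_inner_filter,
    double_log_fit,
    stern_volmer_fit,
)
from .thermo import ThermoParams, interpret_forces, vant_hoff_fit
from .wham import PMFProfile, UmbrellaWindow, UmbrellaWindowSet, analyze_umbrella

__all__ = [
    "read_titration",
    "write_titration",
    "read_cd",
    "write_cd",
    "read_umbrella_windows",
    "write_umbrella_windows",
    "write_pmf",
    "run_pipeline",
    "report_to_json",
    "report_from_json",
]

log = logging.getLogger("quenchbind")

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


def _parse_metadata(path: Path) -> tuple[dict[str, str], str]:
    """Split '#key=value' header lines from the tabular body."""
    meta: dict[str, str] = {}
    body_lines = []
    text = Path(path).read_text()
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            if "=" in stripped:
                key, _, val = stripped[1:].partition("=")
                meta[key.strip()] = val.strip()
            continue
        if stripped:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def _read_table(body: str, path: Path) -> pd.DataFrame:
    if not body.strip():
        raise ValueError(f"{path}: empty file (no data rows)")
    try:
        df = pd.read_csv(_io.StringIO(body), sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ValueError(f"{path}: cannot parse table ({exc})") from exc
    if df.empty:
        raise ValueError(f"{path}: empty file (no data rows)")
    return df


def read_titration(path: str | Path) -> TitrationSeries:
    """Read a titration table.

    Required columns: ``ligand_total`` (units from the ``ligand_units``
    metadata key, default uM; or ``ligand_total_M`` for explicit molar)
    and ``F``. Optional: ``A_ex`` and ``A_em`` (both or neither).
    Metadata: ``temperature_K`` (required), ``P0_M`` or ``P0`` with
    ``conc_units``. Malformed numeric rows are reported by line.
    """
    path = Path(path)
    meta, body = _parse_metadata(path)
    df = _read_table(body, path)
    if "ligand_total_M" in df.columns:
        ligand = df["ligand_total_M"].to_numpy(dtype=float)
    elif "ligand_total" in df.columns:
        unit = meta.get("ligand_units", "uM")
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"{path}: unknown ligand_units {unit!r}")
        ligand = df["ligand_total"].to_numpy(dtype=float) * _UNIT_FACTORS[unit]
    else:
        raise ValueError(
            f"{path}: missing required column ligand_total (or ligand_total_M)"
        )
    if "F" not in df.columns:
        raise ValueError(f"{path}: missing required column F")
    bad = df.index[df["F"].isna() | ~np.isfinite(df["F"].to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(
            f"{path}: malformed intensity in data row(s) {list(bad + 2)}"
        )
    has_ex = "A_ex" in df.columns
    has_em = "A_em" in df.columns
    if has_ex != has_em:
        missing = "A_em" if has_ex else "A_ex"
        raise ValueError(
            f"{path}: absorbance columns must come in pairs; missing {missing}"
        )
    if "temperature_K" not in meta:
        raise ValueError(f"{path}: missing metadata key temperature_K")
    if "P0_M" in meta:
        P0 = float(meta["P0_M"])
    elif "P0" in meta:
        unit = meta.get("conc_units", "uM")
        P0 = float(meta["P0"]) * _UNIT_FACTORS[unit]
    else:
        raise ValueError(f"{path}: missing metadata key P0_M (or P0)")
    if np.any(np.diff(ligand) <= 0):
        raise ValueError(f"{path}: ligand column must be strictly increasing")
    F = df["F"].to_numpy(dtype=float)
    F0 = float(meta["F0"]) if "F0" in meta else (
        float(F[0]) if ligand[0] == 0 else None
    )
    if F0 is None:
        raise ValueError(
            f"{path}: no zero-ligand row and no F0 metadata key"
        )
    return TitrationSeries(
        temperature=float(meta["temperature_K"]),
        P0=P0,
        ligand_total=ligand,
        F=F,
        F0=F0,
        A_ex=df["A_ex"].to_numpy(dtype=float) if has_ex else None,
        A_em=df["A_em"].to_numpy(dtype=float) if has_em else None,
        corrected=meta.get("corrected", "false").lower() == "true",
    )


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    path = Path(path)
    cols = {"ligand_total_M": series.ligand_total, "F": series.F}
    if series.A_ex is not None and series.A_em is not None:
        cols["A_ex"] = series.A_ex
        cols["A_em"] = series.A_em
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={series.temperature:g}\n")
        fh.write(f"# P0_M={series.P0:.10g}\n")
        fh.write(f"# F0={series.F0:.10g}\n")
        fh.write(f"# corrected={'true' if series.corrected else 'false'}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_cd(path: str | Path) -> CDSpectrum:
    """Read a CD spectrum (columns wavelength_nm, theta_mdeg).

    Metadata: ``P_M`` (or ``P`` + ``conc_units``), ``path_cm``, ``n_res``,
    optional ``replicate_id``.
    """
    path = Path(path)
    meta, body = _parse_metadata(path)
    df = _read_table(body, path)
    for col in ("wavelength_nm", "theta_mdeg"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    for key in ("path_cm", "n_res"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata key {key}")
    if "P_M" in meta:
        P = float(meta["P_M"])
    elif "P" in meta:
        P = float(meta["P"]) * _UNIT_FACTORS[meta.get("conc_units", "uM")]
    else:
        raise ValueError(f"{path}: missing metadata key P_M (or P)")
    return CDSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(dtype=float),
        theta_mdeg=df["theta_mdeg"].to_numpy(dtype=float),
        P=P,
        path=float(meta["path_cm"]),
        n_res=int(meta["n_res"]),
        replicate_id=meta.get("replicate_id"),
    )


def write_cd(spec: CDSpectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "theta_mdeg": spec.theta_mdeg}
    )
    with open(path, "w") as fh:
        fh.write(f"# P_M={spec.P:.10g}\n")
        fh.write(f"# path_cm={spec.path:g}\n")
        fh.write(f"# n_res={spec.n_res}\n")
        if spec.replicate_id is not None:
            fh.write(f"# replicate_id={spec.replicate_id}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_umbrella_windows(meta_path: str | Path) -> UmbrellaWindowSet:
    """Read an umbrella-window set from a metadata table.

    The metadata TSV has columns (window_id, center_nm,
    k_spring_kj_mol_nm2, file) with a ``temperature_K`` header key; each
    referenced per-window TSV has columns (time_ps, xi_nm). Relative file
    paths resolve against the metadata file's directory.
    """
    meta_path = Path(meta_path)
    meta, body = _parse_metadata(meta_path)
    df = _read_table(body, meta_path)
    for col in ("window_id", "center_nm", "k_spring_kj_mol_nm2", "file"):
        if col not in df.columns:
            raise ValueError(f"{meta_path}: missing required column {col}")
    windows = []
    for _, row in df.iterrows():
        wpath = meta_path.parent / str(row["file"])
        _, wbody = _parse_metadata(wpath)
        wdf = _read_table(wbody, wpath)
        if "xi_nm" not in wdf.columns:
            raise ValueError(f"{wpath}: missing required column xi_nm")
        windows.append(
            UmbrellaWindow(
                center=float(row["center_nm"]),
                k_spring=float(row["k_spring_kj_mol_nm2"]),
                samples=wdf["xi_nm"].to_numpy(dtype=float),
            )
        )
    return UmbrellaWindowSet(
        windows=windows, temperature=float(meta.get("temperature_K", 298.0))
    )


def write_umbrella_windows(
    ws: UmbrellaWindowSet, outdir: str | Path, dt_ps: float = 1.0
) -> Path:
    """Write per-window TSVs plus the metadata table; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(ws.windows):
        fname = f"window_{i:03d}.tsv"
        t = np.arange(len(w.samples)) * dt_ps
        pd.DataFrame({"time_ps": t, "xi_nm": w.samples}).to_csv(
            outdir / fname, sep="\t", index=False, float_format="%.8g"
        )
        rows.append((i, w.center, w.k_spring, fname))
    meta_path = outdir / "windows_meta.tsv"
    with open(meta_path, "w") as fh:
        fh.write(f"# temperature_K={ws.temperature:g}\n")
        pd.DataFrame(
            rows,
            columns=["window_id", "center_nm", "k_spring_kj_mol_nm2", "file"],
        ).to_csv(fh, sep="\t", index=False)
    return meta_path


def write_pmf(profile: PMFProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "xi_nm": profile.xi_grid,
            "pmf_kj_mol": profile.pmf,
            "se_kj_mol": (
                profile.pmf_se
                if profile.pmf_se is not None
                else np.full_like(profile.pmf, np.nan)
            ),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={profile.temperature:g}\n")
        if profile.delta_g_bind is not None:
            fh.write(f"# delta_g_bind_kj_mol={profile.delta_g_bind:.6g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# JSON report
# ---------------------------------------------------------------------------

def _quench_fit_dict(f: QuenchFit) -> dict:
    return {
        "Ksv": f.Ksv,
        "Ksv_se": f.Ksv_se,
        "intercept": f.intercept,
        "intercept_se": f.intercept_se,
        "r_squared": f.r_squared,
        "abscissa": f.abscissa,
        "warnings": f.warnings,
        "units": {"Ksv": "M^-1"},
    }


def _binding_fit_dict(f: BindingFit) -> dict:
    return {
        "Ka": f.Ka,
        "Ka_se": f.Ka_se,
        "n_hill": f.n_hill,
        "n_hill_se": f.n_hill_se,
        "r_squared": f.r_squared,
        "warnings": f.warnings,
        "units": {"Ka": "M^-1", "n_hill": "dimensionless"},
    }


def _thermo_dict(p: ThermoParams) -> dict:
    return {
        "dH": p.dH,
        "dH_se": p.dH_se,
        "dS": p.dS,
        "dS_se": p.dS_se,
        "r_squared": p.r_squared,
        "dG_by_T": {
            f"{T:g}": {"dG": v, "se": s} for T, (v, s) in p.dG_by_T.items()
        },
        "units": {"dH": "kJ/mol", "dS": "J/(mol K)", "dG": "kJ/mol"},
    }


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def report_from_json(path_or_text: str | Path) -> dict:
    p = Path(path_or_text) if isinstance(path_or_text, Path) else None
    if p is None and "\n" not in str(path_or_text) and Path(str(path_or_text)).exists():
        p = Path(str(path_or_text))
    text = p.read_text() if p is not None else str(path_or_text)
    return json.loads(text)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full analysis pipeline from a configuration.

    ``config`` is a dict (or path to a YAML file) with any subset of:

    - ``titration_files``: list of titration TSVs (one per temperature)
    - ``inner_filter``: apply the inner-filter correction (default true
      when absorbance columns are present)
    - ``cd_files_free`` / ``cd_files_bound``: replicate CD spectra for
      the apo and liganded conditions
    - ``wham``: {metadata_file, n_bins, n_boot, seed, plateau_fraction}
    - ``seed``: master seed for stochastic steps (bootstrap)

    Stages absent from the config are marked "skipped". A failing stage
    is isolated: its section carries the error and the rest still runs.
    Returns the report dict (JSON-serialisable).
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    report: dict = {
        "provenance": {
            "package": "quenchbind",
            "version": __version__,
            "seed": config.get("seed"),
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "input_hashes": {},
        }
    }
    hashes = report["provenance"]["input_hashes"]
    seed = config.get("seed")

    # --- fluorescence titrations -------------------------------------
    tit_files = config.get("titration_files")
    if tit_files:
        try:
            series_list = []
            for f in tit_files:
                hashes[str(f)] = _sha256(f)
                series_list.append(read_titration(f))
            temps = [s.temperature for s in series_list]
            if len(set(temps)) != len(temps):
                raise ValueError(
                    f"inconsistent temperatures across titration files: {temps}"
                )
            apply_ifc = config.get("inner_filter", None)
            quench_sec: dict = {}
            binding_sec: dict = {}
            fits = []
            bfits = []
            for s in series_list:
                if s.A_ex is not None and not s.corrected and apply_ifc in (None, True):
                    s = correct_inner_filter(s)
                elif apply_ifc and s.A_ex is None:
                    raise ValueError(
                        "inner_filter requested but absorbance columns absent"
                    )
                qf = stern_volmer_fit(s)
                # variance-weighted double-log coordinates: robust to the
                # amplified log noise of low-quench points
                bf = double_log_fit(s, weighting="fb2")
                fits.append((s.temperature, qf))
                bfits.append((s.temperature, bf))
                quench_sec[f"{s.temperature:g}"] = _quench_fit_dict(qf)
                binding_sec[f"{s.temperature:g}"] = _binding_fit_dict(bf)
            verdict = classify_mechanism(fits)
            report["stern_volmer"] = quench_sec
            report["binding"] = binding_sec
            report["mechanism"] = {
                "verdict": verdict.verdict,
                "slope_Ksv_vs_T": verdict.slope,
                "slope_se": verdict.slope_se,
                "linearity_ok": {f"{t:g}": ok for t, ok in verdict.linearity_ok.items()},
                "narrative": verdict.narrative,
            }
            if len(bfits) >= 2:
                params = vant_hoff_fit(
                    [(T, f.Ka, f.Ka_se) for T, f in bfits]
                )
                report["thermodynamics"] = _thermo_dict(params)
                forces = interpret_forces(params)
                report["forces"] = {
                    "driving_forces": forces.driving_forces,
                    "endothermic": forces.endothermic,
                    "spontaneous_by_T": {
                        f"{t:g}": ok for t, ok in forces.spontaneous_by_T.items()
                    },
                    "narrative": forces.narrative,
                }
            else:
                report["thermodynamics"] = {
                    "skipped": "needs >= 2 temperatures"
                }
        except Exception as exc:
            log.error("titration stage failed: %s", exc)
            report["stern_volmer"] = {"error": str(exc)}
            report.setdefault("binding", {"error": str(exc)})
            report.setdefault("mechanism", {"error": str(exc)})
    else:
        for key in ("stern_volmer", "binding", "mechanism", "thermodynamics"):
            report[key] = {"skipped": "no titration inputs configured"}

    # --- circular dichroism ------------------------------------------
    cd_free = config.get("cd_files_free")
    cd_bound = config.get("cd_files_bound")
    if cd_free or cd_bound:
        try:
            section: dict = {}
            est_free = est_bound = None
            if cd_free:
                for f in cd_free:
                    hashes[str(f)] = _sha256(f)
                est_free = helix_from_spectra([read_cd(f) for f in cd_free])
                section["free"] = {
                    "helix_percent": est_free.helix_percent,
                    "mre222": est_free.mre222,
                    "se": est_free.se,
                    "warnings": est_free.warnings,
                }
            if cd_bound:
                for f in cd_bound:
                    hashes[str(f)] = _sha256(f)
                est_bound = helix_from_spectra([read_cd(f) for f in cd_bound])
                section["bound"] = {
                    "helix_percent": est_bound.helix_percent,
                    "mre222": est_bound.mre222,
                    "se": est_bound.se,
                    "warnings": est_bound.warnings,
                }
            if est_free is not None and est_bound is not None:
                ch = helix_change(est_free, est_bound)
                section["change"] = {
                    "delta_points": ch.delta_points,
                    "delta_points_se": ch.delta_points_se,
                    "relative_percent": ch.relative_percent,
                    "relative_percent_se": ch.relative_percent_se,
                }
            report["cd_helix"] = section
        except Exception as exc:
            log.error("CD stage failed: %s", exc)
            report["cd_helix"] = {"error": str(exc)}
    else:
        report["cd_helix"] = {"skipped": "no CD inputs configured"}

    # --- umbrella sampling / WHAM ------------------------------------
    wham_cfg = config.get("wham")
    if wham_cfg:
        try:
            meta_file = wham_cfg["metadata_file"]
            hashes[str(meta_file)] = _sha256(meta_file)
            ws = read_umbrella_windows(meta_file)
            profile = analyze_umbrella(
                ws,
                n_bins=int(wham_cfg.get("n_bins", 200)),
                n_boot=int(wham_cfg.get("n_boot", 1000)),
                seed=wham_cfg.get("seed", seed),
                plateau_fraction=float(wham_cfg.get("plateau_fraction", 0.1)),
            )
            report["pmf"] = {
                "delta_g_bind": profile.delta_g_bind,
                "delta_g_bind_se": profile.delta_g_bind_se,
                "n_bins": profile.n_bins,
                "n_iterations": profile.n_iter,
                "residual": profile.residual,
                "temperature_K": profile.temperature,
                "units": {"delta_g_bind": "kJ/mol", "xi": "nm"},
            }
        except Exception as exc:
            log.error("WHAM stage failed: %s", exc)
            report["pmf"] = {"error": str(exc)}
    else:
        report["pmf"] = {"skipped": "no umbrella-sampling inputs configured"}

    return report
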