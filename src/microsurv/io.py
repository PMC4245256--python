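"""Readers and writers: spectra, PDs, parameter files, survival tables.

One tabular dialect throughout: CSV with unit-suffixed headers.  Parameters
and results travel as JSON.  `inf` is accepted (as the string "inf") for
the unbounded threshold and saturation parameters.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .microdose import SingleEventSpectrum, SpecificEnergyPD
from .nontargeted import NTParams
from .synthetic import SurvivalDataset
from .targeted import DSMKParams

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_pd",
    "read_nt_params",
    "write_nt_params",
    "read_dsmk_params",
    "write_dsmk_params",
    "read_survival_csv",
    "write_survival_csv",
    "load_bundled_nt",
    "load_bundled_dsmk",
    "bundled_names",
]

_SPECTRUM_COLS = ["z_Gy", "density_per_Gy"]


class ParseError(ValueError):
    """Malformed input file (missing unit-bearing column or field)."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_spectrum(csv_path) -> SingleEventSpectrum:
    """Read a spectrum CSV (`z_Gy,density_per_Gy`) with its JSON sidecar
    (`<stem>.json` holding site_radius_um, zbar_F_Gy, label)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    _require_columns(df, _SPECTRUM_COLS, csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise ParseError(f"spectrum sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    for key in ("site_radius_um", "zbar_F_Gy"):
        if key not in meta:
            raise ParseError(f"{sidecar}: missing field {key!r}")
    return SingleEventSpectrum(
        site_radius=float(meta["site_radius_um"]),
        zbar_F=float(meta["zbar_F_Gy"]),
        grid=df["z_Gy"].to_numpy(float),
        density=df["density_per_Gy"].to_numpy(float),
        label=str(meta.get("label", "")),
    )


def write_spectrum(spec: SingleEventSpectrum, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"z_Gy": spec.grid, "density_per_Gy": spec.density}).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"site_radius_um": spec.site_radius, "zbar_F_Gy": spec.zbar_F, "label": spec.label},
        indent=2) + "\n")


def write_pd(pdist: SpecificEnergyPD, csv_path) -> None:
    """Dump the continuous part as CSV plus a JSON sidecar with the dose,
    the zero mass and any point masses."""
    csv_path = Path(csv_path)
    pd.DataFrame({"z_Gy": pdist.grid, "density_per_Gy": pdist.density}).to_csv(csv_path, index=False)
    meta = {"dose_Gy": pdist.dose, "zero_mass": pdist.zero_mass,
            "atoms_z_Gy": pdist.atoms_z.tolist(), "atoms_w": pdist.atoms_w.tolist()}
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def _parse_inf(v) -> float:
    if isinstance(v, str) and v.strip().lower() in ("inf", "infinity"):
        return math.inf
    return float(v)


def nt_params_from_dict(d: dict) -> NTParams:
    try:
        return NTParams(
            a1=float(d["a1"]), a2=float(d["a2"]), eta=float(d["eta"]), kappa=float(d["kappa"]),
            z_thre=_parse_inf(d["z_thre_Gy"]), n_population=float(d["n_population"]),
        )
    except KeyError as e:
        raise ParseError(f"nontargeted parameter file missing field {e}") from e


def read_nt_params(path) -> NTParams:
    return nt_params_from_dict(json.loads(Path(path).read_text()))


def write_nt_params(p: NTParams, path) -> None:
    d = {"a1": p.a1, "a2": p.a2, "eta": p.eta, "kappa": p.kappa,
         "z_thre_Gy": "inf" if math.isinf(p.z_thre) else p.z_thre,
         "n_population": p.n_population}
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def dsmk_params_from_dict(d: dict) -> DSMKParams:
    try:
        return DSMKParams(
            alpha0=float(d["alpha0_per_Gy"]), beta0=float(d["beta0_per_Gy2"]),
            r_d=float(d["r_d_um"]), z0=_parse_inf(d["z0_Gy"]), r_n=float(d["r_n_um"]),
            method=str(d.get("method", "saturation")),
        )
    except KeyError as e:
        raise ParseError(f"targeted parameter file missing field {e}") from e


def read_dsmk_params(path) -> DSMKParams:
    return dsmk_params_from_dict(json.loads(Path(path).read_text()))


def write_dsmk_params(p: DSMKParams, path) -> None:
    d = {"alpha0_per_Gy": p.alpha0, "beta0_per_Gy2": p.beta0, "r_d_um": p.r_d,
         "z0_Gy": "inf" if math.isinf(p.z0) else p.z0, "r_n_um": p.r_n, "method": p.method}
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_survival_csv(path) -> SurvivalDataset:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SurvivalDataset.COLUMNS, path)
    return SurvivalDataset(table=df, metadata={"source": str(path)})


def write_survival_csv(ds: SurvivalDataset, path) -> None:
    ds.table.to_csv(Path(path), index=False, float_format="%.10g")


# --- bundled parameter sets -------------------------------------------------

def _bundled(name: str) -> dict:
    ref = resources.files("microsurv").joinpath("params", f"{name}.json")
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled parameter file {name!r}; available: {bundled_names()}")
    return json.loads(ref.read_text())


def bundled_names() -> list[str]:
    root = resources.files("microsurv").joinpath("params")
    return sorted(p.name.removesuffix(".json") for p in root.iterdir() if p.name.endswith(".json"))


def load_bundled_nt(name: str, *, z_thre: float | None = None) -> NTParams:
    """Bundled nontargeted parameter set (``nt_wi38`` or ``nt_bcl2neo``);
    ``z_thre`` overrides the threshold (the two analysed configurations are
    1e-3 Gy and inf)."""
    p = nt_params_from_dict(_bundled(name))
    if z_thre is not None:
        from dataclasses import replace
        p = replace(p, z_thre=z_thre)
    return p


def load_bundled_dsmk(name: str) -> DSMKParams:
    """Bundled targeted-channel parameter set, one per fitted column:
    ``targeted_conventional_zthre_1mGy``, ``targeted_conventional_zthre_inf``,
    ``targeted_bcl2_saturation``, ``targeted_bcl2_adaptive``."""
    return dsmk_params_from_dict(_bundled(name))
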