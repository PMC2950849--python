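"""Reading and writing the package's plain-text interchange formats.

Use-availability records travel as CSV with columns
``individual_id,species,y,bare,height,habitat`` ('.' decimal separator,
UTF-8 header); height may be empty when a species preset omits it. Point
tracks use ``individual_id,species,x,y,t,activity``. Home ranges are
RFC 7946 GeoJSON polygons (ring closure enforced on write), landscapes a
simple ASCII-grid raster, and fit artifacts a draws CSV plus JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .geometry import Polygon
from .rsf_model import (
    FitResult,
    GofReport,
    DicSummary,
    ModelFormula,
    ResponseCurve,
    Standardization,
)

__all__ = [
    "read_records",
    "write_records",
    "write_geojson",
    "read_geojson",
    "write_ascii_grid",
    "write_curves",
    "read_curves",
    "save_fit",
    "load_fit",
    "write_gof",
    "write_selection_table",
]

RECORD_COLUMNS = ["individual_id", "species", "y", "bare", "height", "habitat"]


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV {path} lacks required columns {missing}")
    if "habitat" not in df.columns:
        df["habitat"] = None
    bad = df[(df["bare"] < 0) | (df["bare"] > 1)]
    if len(bad):
        raise ValueError(f"{len(bad)} records have bare outside [0, 1]")
    if (df["height"].dropna() < 0).any():
        raise ValueError("negative vegetation heights in records CSV")
    return df


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    df.reindex(columns=RECORD_COLUMNS).to_csv(path, index=False)


def write_geojson(polygon: Polygon, path: str | Path, **properties) -> None:
    geom = mapping(polygon.to_shapely())  # shapely closes the ring
    feature = {
        "type": "Feature",
        "geometry": geom,
        "properties": properties,
    }
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": [feature]}, indent=1)
    )


def read_geojson(path: str | Path) -> list[Polygon]:
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    out = []
    for f in feats:
        geom = shape(f["geometry"] if "geometry" in f else f)
        out.append(Polygon(np.asarray(geom.exterior.coords)[:-1]))
    return out


def write_ascii_grid(landscape, path: str | Path, layer: str = "bare") -> None:
    """ESRI ASCII-grid export of one landscape layer."""
    arr = landscape.bare_mask.astype(int) if layer == "bare" else landscape.height
    ny, nx = arr.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {landscape.grain}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grid rows run north to south
        np.savetxt(fh, arr[::-1], fmt="%d" if layer == "bare" else "%.2f")


def write_curves(curves: ResponseCurve | list[ResponseCurve], path: str | Path) -> None:
    if isinstance(curves, ResponseCurve):
        curves = [curves]
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "level": c.level,
                    "individual_id": c.individual_id or "",
                    "covariate": c.covariate,
                    "grid": c.grid,
                    "mean": c.mean,
                    "lo80": c.lo80,
                    "hi80": c.hi80,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def _flat_names(fit: FitResult) -> list[str]:
    names = [f"mu[{c}]" for c in fit.columns]
    names += [f"sigma[{c}]" for c in fit.columns]
    names += [f"beta[{i},{c}]" for i in fit.individuals for c in fit.columns]
    names.append("deviance")
    return names


def save_fit(fit: FitResult, prefix: str | Path) -> None:
    """Persist a fit as <prefix>_draws.csv (one row per draw) + <prefix>.json."""
    prefix = Path(prefix)
    nd = fit.n_draws
    flat = np.column_stack(
        [fit.mu, fit.sigma, fit.beta.reshape(nd, -1), fit.deviance]
    )
    pd.DataFrame(flat, columns=_flat_names(fit)).to_csv(
        prefix.with_name(prefix.name + "_draws.csv"), index=False,
        float_format="%.17g",  # draws must round-trip bit-exactly
    )
    meta = {
        "formula": fit.formula.name,
        "columns": list(fit.columns),
        "individuals": list(fit.individuals),
        "n_chains": fit.n_chains,
        "standardization": {
            "mean": dict(fit.standardization.mean),
            "sd": dict(fit.standardization.sd),
        },
        "rhat": fit.rhat,
        "ess": fit.ess,
        "warnings": fit.warnings,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_fit(prefix: str | Path) -> FitResult:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(
        prefix.with_name(prefix.name + "_draws.csv"), float_precision="round_trip"
    )
    cols = meta["columns"]
    K = len(cols)
    inds = meta["individuals"]
    mu = df[[f"mu[{c}]" for c in cols]].to_numpy()
    sigma = df[[f"sigma[{c}]" for c in cols]].to_numpy()
    beta = df[
        [f"beta[{i},{c}]" for i in inds for c in cols]
    ].to_numpy().reshape(len(df), len(inds), K)
    return FitResult(
        mu=mu,
        sigma=sigma,
        beta=beta,
        deviance=df["deviance"].to_numpy(),
        n_chains=meta["n_chains"],
        columns=tuple(cols),
        individuals=tuple(inds),
        standardization=Standardization(
            mean=meta["standardization"]["mean"], sd=meta["standardization"]["sd"]
        ),
        formula=ModelFormula.from_string(meta["formula"]),
        rhat=meta.get("rhat", {}),
        ess=meta.get("ess", {}),
        warnings=meta.get("warnings", []),
    )


def write_gof(report: GofReport, path: str | Path, **extra) -> None:
    payload = {
        "bayes_p": report.bayes_p,
        "t_obs_mean": float(np.mean(report.t_obs)),
        "t_rep_mean": float(np.mean(report.t_rep)),
        "n_draws": int(len(report.t_obs)),
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_selection_table(table, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.2f")
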