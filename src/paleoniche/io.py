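"""Readers and writers: camps CSV, site CSV, NetCDF stacks, model JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .archaeo import ArchaeoSite
from .grid import CampRecord, GridSpec, LayerStack, camps_from_frame
from .niche import FeatureBasis, NicheModel


def read_camps_csv(path) -> list[CampRecord]:
    return camps_from_frame(pd.read_csv(path))


def write_camps_csv(camps: list[CampRecord], path) -> None:
    pd.DataFrame([{"id": c.id, "lon": c.lon, "lat": c.lat,
                   "population_size": c.population_size,
                   "excluded": c.excluded} for c in camps]).to_csv(path, index=False)


def read_sites_csv(path) -> list[ArchaeoSite]:
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        fi = rec.get("farming_indicators", "")
        fi = frozenset(x for x in str(fi).split(";") if x) if pd.notna(fi) else frozenset()
        lab = rec.get("lab_code")
        out.append(ArchaeoSite(
            id=str(rec["id"]), lon=float(rec["lon"]), lat=float(rec["lat"]),
            age_bp=float(rec["age_bp"]), age_error=float(rec.get("age_error", 0)),
            material=str(rec.get("material", "other")),
            lab_code=None if lab is None or pd.isna(lab) else str(lab),
            stratigraphy_ok=bool(rec.get("stratigraphy_ok", True)),
            farming_indicators=fi,
            chronoculture=str(rec.get("chronoculture", "other")),
            has_lithics=bool(rec.get("has_lithics", False)),
            pottery=bool(rec.get("pottery", False)),
            disputed=bool(rec.get("disputed", False))))
    return out


def write_sites_csv(sites: list[ArchaeoSite], path) -> None:
    pd.DataFrame([{
        "id": s.id, "lon": s.lon, "lat": s.lat, "age_bp": s.age_bp,
        "age_error": s.age_error, "material": s.material, "lab_code": s.lab_code,
        "stratigraphy_ok": s.stratigraphy_ok,
        "farming_indicators": ";".join(sorted(s.farming_indicators)),
        "chronoculture": s.chronoculture, "has_lithics": s.has_lithics,
        "pottery": s.pottery, "disputed": s.disputed,
    } for s in sites]).to_csv(path, index=False)


def stack_to_netcdf(stack: LayerStack, path) -> None:
    """Write a LayerStack (grid metadata in attrs, layers as age_bp-indexed vars)."""
    g = stack.grid
    names = stack.layer_names()
    data = {n: (("age_bp", "row", "col"),
                np.stack([stack.layers[a][n] for a in stack.ages]))
            for n in names}
    data["land_mask"] = (("row", "col"), g.land_mask.astype(np.int8))
    ds = xr.Dataset(data, coords={"age_bp": stack.ages})
    ds.attrs.update(lon_min=g.lon_min, lon_max=g.lon_max, lat_min=g.lat_min,
                    lat_max=g.lat_max, cell_size=g.cell_size,
                    categorical=",".join(sorted(stack.categorical)))
    ds.to_netcdf(path, engine="scipy")


def stack_from_netcdf(path) -> LayerStack:
    ds = xr.open_dataset(path, engine="scipy")
    at = ds.attrs
    mask = ds["land_mask"].values.astype(bool)
    grid = GridSpec(lon_min=float(at["lon_min"]), lon_max=float(at["lon_max"]),
                    lat_min=float(at["lat_min"]), lat_max=float(at["lat_max"]),
                    cell_size=float(at["cell_size"]), land_mask=mask)
    ages = [int(a) for a in ds["age_bp"].values]
    names = [v for v in ds.data_vars if v != "land_mask"]
    layers = {age: {n: ds[n].isel(age_bp=k).values for n in names}
              for k, age in enumerate(ages)}
    cat = set(x for x in str(at.get("categorical", "")).split(",") if x)
    ds.close()
    return LayerStack(grid=grid, ages=ages, layers=layers, categorical=cat)


def model_to_json(model: NicheModel, path) -> None:
    b = model.basis
    payload = {
        "mode": model.mode,
        "weights": list(map(float, model.weights)),
        "intercept": model.intercept,
        "regularization": model.regularization,
        "n1": model.n1, "n0": model.n0, "threshold": model.threshold,
        "basis": {
            "predictor_names": b.predictor_names,
            "categorical": sorted(b.categorical),
            "n_knots": b.n_knots,
            "feature_classes": list(b.feature_classes),
            "clamp_range": {k: list(v) for k, v in b.clamp_range.items()},
            "knots": {k: list(map(float, v)) for k, v in b.knots.items()},
            "levels": {k: list(map(float, v)) for k, v in b.levels.items()},
            "feature_names": b.feature_names_,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def model_from_json(path) -> NicheModel:
    d = json.loads(Path(path).read_text())
    bd = d["basis"]
    basis = FeatureBasis(predictor_names=bd["predictor_names"],
                         categorical=set(bd["categorical"]),
                         n_knots=bd["n_knots"],
                         feature_classes=tuple(bd["feature_classes"]))
    basis.clamp_range = {k: tuple(v) for k, v in bd["clamp_range"].items()}
    basis.knots = {k: np.asarray(v) for k, v in bd["knots"].items()}
    basis.levels = {k: np.asarray(v) for k, v in bd["levels"].items()}
    basis.feature_names_ = bd["feature_names"]
    return NicheModel(basis=basis, weights=np.asarray(d["weights"]),
                      intercept=d["intercept"], regularization=d["regularization"],
                      n1=d["n1"], n0=d["n0"], mode=d["mode"],
                      threshold=d["threshold"])
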