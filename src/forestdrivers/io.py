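"""Readers, writers, configuration and the top-level pipeline runner.

Tables travel as CSV or GeoJSON point collections; rasters as ESRI ASCII
grids (plain-text, with the CRS tag in a ``.crs`` sidecar); configuration
as YAML; run manifests as JSON with content hashes of every stage output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from forestdrivers.dataset import RESERVED, SpatialDataset
from forestdrivers.errors import ValidationError
from forestdrivers.grid import Raster

logger = logging.getLogger(__name__)

__all__ = [
    "read_spatial_dataset",
    "write_spatial_dataset",
    "read_ascii_grid",
    "write_ascii_grid",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# spatial dataset I/O
# ---------------------------------------------------------------------------

def read_spatial_dataset(
    path: str | Path, crs: str = "local-meters"
) -> SpatialDataset:
    """Read a spatial dataset from CSV or GeoJSON (by file extension).

    Validates unique ids and finite coordinates; non-finite covariate
    values are reported (logged), not silently accepted.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table = pd.read_csv(path)
        missing = [c for c in RESERVED if c not in table.columns]
        if missing:
            raise ValidationError(f"{path.name}: missing columns {missing}")
    elif path.suffix.lower() in (".geojson", ".json"):
        payload = json.loads(path.read_text())
        if payload.get("type") != "FeatureCollection":
            raise ValidationError(f"{path.name}: not a GeoJSON FeatureCollection")
        crs = payload.get("crs", {}).get("properties", {}).get("name", crs)
        rows = []
        for feat in payload["features"]:
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValidationError("spatial dataset features must be Points")
            x, y = geom["coordinates"][:2]
            rows.append({**feat.get("properties", {}), "x": x, "y": y})
        table = pd.DataFrame(rows)
        if "id" not in table.columns:
            raise ValidationError(f"{path.name}: features lack an 'id' property")
    else:
        raise ValidationError(f"unsupported spatial dataset format: {path.suffix}")
    ds = SpatialDataset(table, crs=crs)
    bad = ds.non_finite_report()
    bad = bad[bad > 0]
    if len(bad):
        logger.warning(
            "%s: non-finite values in variables %s", path.name, dict(bad)
        )
    return ds


def write_spatial_dataset(ds: SpatialDataset, path: str | Path) -> Path:
    """Write a spatial dataset as CSV or GeoJSON points (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".csv":
        ds.table.to_csv(path, index=False)
        return path
    if path.suffix.lower() in (".geojson", ".json"):
        features = []
        for _, row in ds.table.iterrows():
            props = {
                k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in row.items()
                if k not in ("x", "y")
            }
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(row["x"]), float(row["y"])],
                    },
                    "properties": props,
                }
            )
        payload = {
            "type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": ds.crs}},
            "features": features,
        }
        path.write_text(json.dumps(payload))
        return path
    raise ValidationError(f"unsupported spatial dataset format: {path.suffix}")


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid + CRS sidecar)
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0) -> Path:
    """Write a raster as an ESRI ASCII grid with a ``.crs`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows, cols = raster.shape
    data = raster.data.astype(float).copy()
    invalid = ~raster.mask_valid()
    data[invalid] = nodata
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {raster.x_origin}\n"
        f"yllcorner {raster.y_origin - rows * raster.cell_size}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v!r}" for v in map(float, row)) for row in data)
    path.write_text(header + body + "\n")
    path.with_suffix(path.suffix + ".crs").write_text(raster.crs + "\n")
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, value = lines[i].split()
        header[key.lower()] = float(value)
        i += 1
    data = np.loadtxt(lines[i:])
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    crs_path = path.with_suffix(path.suffix + ".crs")
    crs = crs_path.read_text().strip() if crs_path.exists() else "local-meters"
    rows = int(header["nrows"])
    return Raster(
        data,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + rows * header["cellsize"],
        cell_size=header["cellsize"],
        crs=crs,
    )


# ---------------------------------------------------------------------------
# pipeline configuration and runner
# ---------------------------------------------------------------------------

# raster-driven stages (rates / frequencies / trend / dasymetric) run
# through their own subcommands; the pipeline chain covers the grid stages
KNOWN_STAGES = ("simulate", "gwrf", "assess")


@dataclass
class PipelineConfig:
    """Validated top-level pipeline configuration."""

    stages: dict
    seed: int
    out_dir: Path
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("master seed must be an integer")
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValidationError(f"unknown pipeline stage(s): {sorted(unknown)}")
        if not self.stages:
            raise ValidationError("pipeline config declares no stages")
        for stage, params in self.stages.items():
            for key in ("input", "dataset", "path"):
                ref = (params or {}).get(key)
                if ref is not None and not Path(ref).exists():
                    raise ValidationError(f"stage {stage!r}: missing file {ref}")
        if "degree" in self.crs.lower():
            raise ValidationError("CRS must be projected (meters), not geographic")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("pipeline config must be a YAML mapping")
    return PipelineConfig(
        stages=raw.get("stages", {}),
        seed=raw.get("seed", 0),
        out_dir=Path(raw.get("out_dir", "outputs")),
        crs=raw.get("crs", "local-meters"),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Supported chain: ``simulate`` (synthetic spatial dataset + ground
    truth) -> ``gwrf`` (LVI / YHAT / ACC surfaces) -> ``assess``
    (clustering + per-variable hypothesis table). Returns the manifest,
    which is also written to ``manifest.json`` in the output directory
    with content hashes of every output.
    """
    from forestdrivers import assessment, gwrf, synthetic
    from forestdrivers.weights import KernelSpec

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(config.seed), "stages": {}, "outputs": {}}
    dataset = None
    gwrf_result = None

    order = [s for s in KNOWN_STAGES if s in config.stages]
    for stage in order:
        params = dict(config.stages.get(stage) or {})
        if stage == "simulate":
            spec = synthetic.two_region_spec(
                n_cells=int(params.get("n_cells", 400)),
                effect=float(params.get("effect", 2.0)),
                noise_sd=float(params.get("noise_sd", 0.5)),
                n_covariates=int(params.get("n_covariates", 6)),
                seed=int(params.get("seed", config.seed)),
            )
            dataset, truth = synthetic.generate_spatial_dataset(spec)
            p1 = write_spatial_dataset(dataset, out_dir / "dataset.csv")
            p2 = out_dir / "truth.csv"
            truth.to_csv(p2, index=False)
            manifest["outputs"]["dataset"] = str(p1)
            manifest["outputs"]["truth"] = str(p2)
            manifest["stages"]["simulate"] = {"n_cells": len(dataset)}
        elif stage == "gwrf":
            if dataset is None:
                path = params.get("dataset")
                if path is None:
                    raise ValidationError(
                        "gwrf stage needs a 'dataset' file or an upstream simulate stage"
                    )
                dataset = read_spatial_dataset(path)
            cfg = gwrf.GwrfConfig(
                dep=params.get("dep", "rate"),
                kernel=KernelSpec(
                    kernel_type=params.get("kernel_type", "adaptive"),
                    bandwidth=params.get("bandwidth", 100),
                ),
                task=params.get("task", "regression"),
                n_trees=int(params.get("n_trees", 500)),
                upsample=bool(params.get("upsample", True)),
                seed=int(params.get("seed", config.seed)),
            )
            gwrf_result = gwrf.fit_gwrf(dataset, cfg)
            p = out_dir / "gwrf_surfaces.csv"
            gwrf_result.table.to_csv(p, index=False)
            manifest["outputs"]["gwrf_surfaces"] = str(p)
            manifest["stages"]["gwrf"] = {
                "n_locations": len(gwrf_result.table),
                "n_skipped": gwrf_result.n_skipped,
                "bandwidth": cfg.kernel.bandwidth,
            }
        elif stage == "assess":
            if gwrf_result is None:
                raise ValidationError(
                    "assess stage needs an upstream gwrf stage in the same run"
                )
            dep = gwrf_result.config.dep
            rates = np.abs(dataset.table[dep].to_numpy(dtype=float))
            clus = assessment.cluster_lvi(
                gwrf_result.lvi_matrix(),
                rates,
                k=params.get("k"),
                n_ref=int(params.get("n_ref", 20)),
                seed=int(params.get("seed", config.seed)),
                cell_area_ha=float(params.get("cell_area_ha", 400.0)),
            )
            p1 = out_dir / "clusters.csv"
            pd.DataFrame(
                {"id": dataset.ids, "cluster": clus.labels,
                 "selected": clus.selected_mask()}
            ).to_csv(p1, index=False)
            p2 = out_dir / "cluster_summary.csv"
            clus.cluster_summary.to_csv(p2, index=False)
            inside = dataset.table.loc[clus.selected_mask(), dataset.covariates(dep)]
            outside = dataset.table.loc[~clus.selected_mask(), dataset.covariates(dep)]
            table = assessment.hypothesis_table(inside, outside)
            p3 = out_dir / "hypothesis_table.csv"
            table.to_csv(p3, index=False)
            manifest["outputs"]["clusters"] = str(p1)
            manifest["outputs"]["cluster_summary"] = str(p2)
            manifest["outputs"]["hypothesis_table"] = str(p3)
            manifest["stages"]["assess"] = {"k": clus.k}
    manifest["hashes"] = {
        name: _sha256(Path(p)) for name, p in manifest["outputs"].items()
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
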