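"""Grid/layer data model, normalization, and file I/O.

All spatial layers in a cumulative-impact (CI) assessment share one regular
square grid. Human-use intensity layers and environmental-component presence
layers are normalized to [0, 1] before entering the CI model; nodata cells
are carried as a boolean mask and excluded from every sum, percentile and
index denominator downstream.

Rasters are exchanged as single-band float32 TIFF files (NaN encodes nodata)
with a JSON sidecar holding the grid geometry (origin, cell size, nodata
value); the sensitivity table is a CSV with columns
``use_id,pressure_id,env_id,score,distance_km,confidence``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

LAYER_ROLES = ("use_intensity", "env_presence", "pressure_intensity", "impact", "index")

SENSITIVITY_COLUMNS = ("use_id", "pressure_id", "env_id", "score", "distance_km", "confidence")

MAX_DISTANCE_KM = 50.0


class ValidationError(ValueError):
    """An input failed referential-integrity or range validation."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by all layers: a north-up, row-major regular square grid.

    Cell (0, 0) sits at the top-left corner; ``origin`` is the (x, y)
    coordinate of that corner and distances are measured between cell
    centers. ``nodata_mask`` is True where the domain carries no value
    (land cells in a marine study area).
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and one column")
        if self.cell_size_km <= 0:
            raise ValidationError("cell_size_km must be positive")
        if self.nodata_mask is not None:
            mask = np.asarray(self.nodata_mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValidationError("nodata_mask shape does not match grid")
            object.__setattr__(self, "nodata_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def valid_mask(self) -> np.ndarray:
        if self.nodata_mask is None:
            return np.ones(self.shape, dtype=bool)
        return ~self.nodata_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped (n_rows, n_cols)."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * self.cell_size_km
        y = y0 - (rows + 0.5) * self.cell_size_km
        return np.meshgrid(x, y)

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_km, other.cell_size_km)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Layer:
    """One raster layer bound to a grid.

    ``role`` documents the layer's place in the model; use-intensity and
    presence layers are expected in [0, 1] after normalization.
    """

    grid: GridSpec
    values: np.ndarray
    role: str = "index"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"layer shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.role not in LAYER_ROLES:
            raise ValidationError(f"unknown layer role {self.role!r}")

    def copy_with(self, values: np.ndarray, role: str | None = None) -> "Layer":
        return Layer(self.grid, np.array(values, dtype=float), role or self.role)

    def masked(self) -> np.ndarray:
        """Values with nodata cells set to NaN."""
        out = self.values.copy()
        out[~self.grid.valid_mask] = np.nan
        return out


@dataclass(frozen=True)
class SensitivityRecord:
    """One expert-elicited (use, pressure, component) sensitivity relationship.

    ``score`` is the sensitivity s(U, P, E) in [0, 1]; ``distance_km`` the
    pressure distance over which the use's pressure propagates (0-50 km);
    ``confidence`` the expert's reliability c(U, P, E) in [0, 1].
    """

    use_id: str
    pressure_id: str
    env_id: str
    score: float
    distance_km: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(
                f"score {self.score} out of [0,1] for "
                f"({self.use_id},{self.pressure_id},{self.env_id})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"confidence {self.confidence} out of [0,1] for "
                f"({self.use_id},{self.pressure_id},{self.env_id})"
            )
        if not 0.0 <= self.distance_km <= MAX_DISTANCE_KM:
            raise ValidationError(
                f"distance_km {self.distance_km} out of [0,{MAX_DISTANCE_KM:g}] for "
                f"({self.use_id},{self.pressure_id},{self.env_id})"
            )

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.use_id, self.pressure_id, self.env_id)


@dataclass
class CIDataset:
    """Complete model input: grid, use layers, component layers, sensitivities."""

    grid: GridSpec
    uses: dict[str, Layer]
    envs: dict[str, Layer]
    sensitivities: list[SensitivityRecord] = field(default_factory=list)

    def validate(self) -> "CIDataset":
        if not self.uses or not self.envs:
            raise ValidationError("dataset needs at least one use and one env layer")
        for name, layer in {**self.uses, **self.envs}.items():
            if not layer.grid.same_geometry(self.grid):
                raise ValidationError(f"layer {name!r} does not share the dataset grid")
        seen: set[tuple[str, str, str]] = set()
        for rec in self.sensitivities:
            if rec.use_id not in self.uses:
                raise ValidationError(f"sensitivity record references absent use_id {rec.use_id!r}")
            if rec.env_id not in self.envs:
                raise ValidationError(f"sensitivity record references absent env_id {rec.env_id!r}")
            if rec.triple in seen:
                raise ValidationError(f"duplicate sensitivity triple {rec.triple}")
            seen.add(rec.triple)
        return self


def normalize_layer(layer: Layer, mode: str = "linear") -> Layer:
    """Rescale a layer to [0, 1].

    ``linear`` divides by the layer maximum; ``log`` maps x to
    log(1+x)/log(1+max), the heavier compression used for skewed intensity
    layers (shipping density, fishing effort). An all-zero layer is passed
    through unchanged; negative values are rejected. Nodata is preserved.
    Both modes are idempotent and monotone.
    """
    if mode not in ("linear", "log"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    valid = layer.grid.valid_mask
    vals = layer.values[valid]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValidationError("layer has no finite value to normalize")
    if (finite < 0).any():
        raise ValidationError("negative values cannot be normalized")
    vmax = finite.max()
    if vmax == 0:
        logger.warning("normalize_layer: all-zero layer returned unchanged")
        return layer.copy_with(layer.values)
    if vmax == 1.0:
        # already normalized (unit maximum): pass through, so normalization
        # is idempotent in both modes
        return layer.copy_with(layer.values)
    out = layer.values.astype(float).copy()
    if mode == "linear":
        out[valid] = out[valid] / vmax
    else:
        out[valid] = np.log1p(out[valid]) / np.log1p(vmax)
    return layer.copy_with(out)


# ---------------------------------------------------------------------------
# file I/O


def write_layer(layer: Layer, path: str | Path) -> Path:
    """Write a layer as float32 single-band TIFF + JSON grid sidecar.

    Nodata cells are written as NaN; the sidecar records origin and cell
    size so a round trip reconstructs the GridSpec. Output is bit-identical
    across repeated calls on the same input.
    """
    path = Path(path)
    data = layer.masked().astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = {
        "n_rows": layer.grid.n_rows,
        "n_cols": layer.grid.n_cols,
        "cell_size_km": layer.grid.cell_size_km,
        "origin": list(layer.grid.origin),
        "nodata": "nan",
        "role": layer.role,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, sort_keys=True))
    return path


def read_layer(path: str | Path, grid: GridSpec | None = None) -> Layer:
    """Read a layer written by :func:`write_layer`; NaN cells become nodata."""
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta_path = path.with_suffix(path.suffix + ".json")
    role = "index"
    cell_size, origin = 1.0, (0.0, 0.0)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        cell_size = meta.get("cell_size_km", 1.0)
        origin = tuple(meta.get("origin", (0.0, 0.0)))
        role = meta.get("role", "index")
    nodata = ~np.isfinite(data)
    if grid is None:
        grid = GridSpec(
            data.shape[0], data.shape[1], cell_size, origin,
            nodata_mask=nodata if nodata.any() else None,
        )
    data = np.where(nodata, 0.0, data)
    return Layer(grid, data, role)


def read_sensitivity_table(path: str | Path) -> list[SensitivityRecord]:
    """Parse the sensitivity CSV, validating ranges row by row."""
    df = pd.read_csv(path)
    missing = set(SENSITIVITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sensitivity table missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                SensitivityRecord(
                    str(row.use_id), str(row.pressure_id), str(row.env_id),
                    float(row.score), float(row.distance_km), float(row.confidence),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from err
    return records


def write_sensitivity_table(records: Iterable[SensitivityRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(SENSITIVITY_COLUMNS))
    df.to_csv(path, index=False)
    return path


def read_dataset(config: str | Path | Mapping) -> CIDataset:
    """Assemble and validate a CIDataset from a YAML config or mapping.

    Config schema::

        grid: {cell_size_km: 1.0}        # optional override
        uses: {use_id: {path: u.tif, normalize: linear|log|none}, ...}
        envs: {env_id: {path: e.tif}, ...}
        sensitivity_table: sens.csv

    Layers are normalized at load time (default linear); all rasters must
    share one grid geometry.
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        cfg = yaml.safe_load(cfg_path.read_text())
        base = cfg_path.parent
    else:
        cfg = dict(config)
        base = Path(cfg.get("base_dir", "."))

    def _load(entry: Mapping | str, role: str) -> Layer:
        if isinstance(entry, str):
            entry = {"path": entry}
        layer = read_layer(base / entry["path"])
        layer.role = role
        mode = entry.get("normalize", "linear")
        if mode != "none":
            layer = normalize_layer(layer, mode)
        return layer

    uses = {uid: _load(e, "use_intensity") for uid, e in cfg["uses"].items()}
    envs = {eid: _load(e, "env_presence") for eid, e in cfg["envs"].items()}
    grid = next(iter(uses.values())).grid
    for name, layer in {**uses, **envs}.items():
        if not layer.grid.same_geometry(grid):
            raise ValidationError(f"raster {name!r} does not share the common grid")
        layer.grid = grid
    sens = read_sensitivity_table(base / cfg["sensitivity_table"])
    return CIDataset(grid, uses, envs, sens).validate()


def write_dataset(ds: CIDataset, out_dir: str | Path) -> Path:
    """Write a dataset as TIFF layers + CSV table + YAML config under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg: dict = {"uses": {}, "envs": {}, "sensitivity_table": "sensitivity.csv"}
    for uid, layer in ds.uses.items():
        write_layer(layer, out_dir / f"use_{uid}.tif")
        cfg["uses"][uid] = {"path": f"use_{uid}.tif", "normalize": "none"}
    for eid, layer in ds.envs.items():
        write_layer(layer, out_dir / f"env_{eid}.tif")
        cfg["envs"][eid] = {"path": f"env_{eid}.tif", "normalize": "none"}
    write_sensitivity_table(ds.sensitivities, out_dir / "sensitivity.csv")
    (out_dir / "dataset.yml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out_dir / "dataset.yml"
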