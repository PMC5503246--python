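"""Spatial uncertainty indicators: data availability (DAI) and local
sensitivity confidence (LSCI).

DAI maps where the input datasets actually declare coverage. Each dataset
(a use or component layer) declares the gazetteer regions it covers; per
cell the DAI is the fraction (mean mode, in [0, 1]) or raw count (sum
mode) of datasets whose declared regions contain the cell center:

    DAI(cell) = ( sum_i a(U_i) + sum_k a(E_k) ) / (l + n)

LSCI maps where the expert knowledge behind the index is most reliable:
the impact-weighted mean of the per-relationship confidences,

    LSCI(cell) = sum c(U,P,E) * ci(U,P,E) / sum ci(U,P,E),

over all (use, pressure, component) triples contributing at that cell;
cells with no impact are nodata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .ci import CIResult
from .datamodel import GridSpec, Layer, SensitivityRecord, ValidationError

logger = logging.getLogger(__name__)

SCALES = ("marine_region", "national", "sub_national")


@dataclass
class Gazetteer:
    """Named coverage regions: term -> polygon, each with a hierarchy scale."""

    regions: dict[str, BaseGeometry] = field(default_factory=dict)
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, geom in self.regions.items():
            if not geom.is_valid:
                raise ValidationError(f"gazetteer term {term!r} has invalid geometry")

    @classmethod
    def from_geojson(cls, path: str | Path) -> "Gazetteer":
        """Read a FeatureCollection with properties {term, scale}."""
        fc = json.loads(Path(path).read_text())
        regions, hierarchy = {}, {}
        for feat in fc["features"]:
            term = feat["properties"]["term"]
            if term in regions:
                raise ValidationError(f"duplicate gazetteer term {term!r}")
            regions[term] = shapely_shape(feat["geometry"])
            hierarchy[term] = feat["properties"].get("scale", "marine_region")
        return cls(regions, hierarchy)

    def to_geojson(self, path: str | Path) -> Path:
        feats = [
            {
                "type": "Feature",
                "properties": {"term": term, "scale": self.hierarchy.get(term, "marine_region")},
                "geometry": json.loads(shapely.to_geojson(geom)),
            }
            for term, geom in self.regions.items()
        ]
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        return Path(path)


@dataclass(frozen=True)
class CoverageDeclaration:
    """The gazetteer terms one dataset (use or component layer) covers."""

    dataset_id: str
    terms: frozenset[str]

    @staticmethod
    def read_csv(path: str | Path) -> list["CoverageDeclaration"]:
        """CSV with columns dataset_id, terms (semicolon-separated)."""
        df = pd.read_csv(path)
        return [
            CoverageDeclaration(
                str(r.dataset_id),
                frozenset(t for t in str(r.terms).split(";") if t),
            )
            for r in df.itertuples()
        ]

    @staticmethod
    def write_csv(decls: list["CoverageDeclaration"], path: str | Path) -> Path:
        pd.DataFrame(
            {
                "dataset_id": [d.dataset_id for d in decls],
                "terms": [";".join(sorted(d.terms)) for d in decls],
            }
        ).to_csv(path, index=False)
        return Path(path)


def availability_layer(
    decl: CoverageDeclaration, gaz: Gazetteer, grid: GridSpec
) -> Layer:
    """Binary layer: 1 where the cell center falls inside the union of the
    declared terms' geometries."""
    unknown = decl.terms - set(gaz.regions)
    if unknown:
        raise ValidationError(
            f"declaration {decl.dataset_id!r} references unknown terms {sorted(unknown)}"
        )
    if not decl.terms:
        logger.warning("declaration %r has no terms; availability is zero", decl.dataset_id)
        return Layer(grid, np.zeros(grid.shape), role="index")
    union = shapely.union_all([gaz.regions[t] for t in decl.terms])
    x, y = grid.cell_centers()
    inside = shapely.contains_xy(union, x.ravel(), y.ravel()).reshape(grid.shape)
    return Layer(grid, inside.astype(float), role="index")


def dai(
    decls: list[CoverageDeclaration],
    gaz: Gazetteer,
    grid: GridSpec,
    mode: str = "mean",
) -> Layer:
    """Data availability index over all declared datasets.

    ``mean`` (default) gives the per-cell fraction of covering datasets in
    [0, 1]; ``sum`` the raw count in [0, l+n].
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown DAI mode {mode!r}")
    if not decls:
        raise ValidationError("DAI needs at least one coverage declaration")
    count = np.zeros(grid.shape)
    for decl in decls:
        count += availability_layer(decl, gaz, grid).values
    vals = count / len(decls) if mode == "mean" else count
    vals[~grid.valid_mask] = 0.0
    return Layer(grid, vals, role="index")


def lsci(res: CIResult, sens: list[SensitivityRecord] | None = None) -> Layer:
    """Local sensitivity confidence index: impact-weighted mean confidence.

    Cells with zero summed impact carry no confidence information and are
    returned as NaN (nodata). The result is invariant to uniform rescaling
    of all impacts and bounded by the min/max confidence of contributing
    triples.
    """
    sens = sens if sens is not None else res.triples
    if len(sens) != res.impact_stack.shape[0]:
        raise ValidationError("confidence list does not match the impact stack")
    conf = np.array([r.confidence for r in sens])
    stack = res.impact_stack
    denom = stack.sum(axis=0)
    numer = np.tensordot(conf, stack, axes=(0, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)
    vals[~res.ci_map.grid.valid_mask] = np.nan
    return Layer(res.ci_map.grid, vals, role="index")


def lsci_coverage_report(lsci_layer: Layer, thresholds: tuple[float, ...] = (0.8,)) -> pd.DataFrame:
    """Share of impacted cells at or above each confidence threshold."""
    vals = lsci_layer.values[lsci_layer.grid.valid_mask]
    vals = vals[np.isfinite(vals)]
    rows = []
    for thr in thresholds:
        pct = 100.0 * (vals >= thr).mean() if vals.size else float("nan")
        rows.append({"threshold": thr, "pct_impacted_cells": pct})
    return pd.DataFrame(rows)
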