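"""Extended cumulative-impact (CI) index.

Per grid cell the index combines, over every (use U, pressure P, component E)
sensitivity relationship, the product of

* the expert sensitivity score s(U, P, E),
* the spatially spread pressure intensity — the use footprint convolved with
  a 2D Gaussian kernel whose reach is the elicited pressure distance —
  passed through an ecosystem response function rf, and
* the component presence d(E) (binary for fixed habitats, a probability for
  mobile species).

Co-occurring impacts in a cell are blended between the additive model
(their sum) and the dominant model (their maximum) by the multi-stressor
combination factor mscf:

    CI(cell) = (1 - mscf) * sum_t I_t(cell) + mscf * max_t I_t(cell)

The response function interpolates between a linear response (nr = 0) and a
threshold (sigmoid) response (nr = 1) whose inflection sits at the skewness
parameter sr:

    rf(x) = (1 - nr) * x + nr * L(x),   L a logistic renormalized so that
                                        L(0) = 0 and L(1) = 1.

The baseline run of the model is (nr = 0, mscf = 0): linear response,
additive combination.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .datamodel import CIDataset, Layer, SensitivityRecord

logger = logging.getLogger(__name__)

#: logistic steepness of the threshold response; the sigmoid transitions
#: over roughly +/- 3/steepness around the inflection point sr
DEFAULT_STEEPNESS = 10.0

#: mapping from the elicited pressure distance to the Gaussian sigma; with
#: sigma = distance/3 the elicited distance is the ~3-sigma effective reach
DEFAULT_SIGMA_DIVISOR = 3.0


@dataclass(frozen=True)
class ResponseParams:
    """Ecosystem response: nr in [0,1] (linear -> threshold), sr in [0.3, 0.7]."""

    nr: float = 0.0
    sr: float = 0.5
    steepness: float = DEFAULT_STEEPNESS

    def __post_init__(self) -> None:
        if not 0.0 <= self.nr <= 1.0:
            raise ValueError(f"nr {self.nr} out of [0,1]")
        if not 0.3 <= self.sr <= 0.7:
            raise ValueError(f"sr {self.sr} out of [0.3,0.7]")


@dataclass(frozen=True)
class CombinationParams:
    """Multi-stressor combination: mscf 0 = additive, 1 = dominant."""

    mscf: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mscf <= 1.0:
            raise ValueError(f"mscf {self.mscf} out of [0,1]")


@dataclass
class CIResult:
    """CI map, per-triple impact stack and summed per-triple contributions."""

    ci_map: Layer
    impact_stack: np.ndarray              # (n_triples, n_rows, n_cols)
    triples: list[SensitivityRecord]
    triple_totals: np.ndarray             # summed impact per triple over valid cells
    response: ResponseParams
    combination: CombinationParams


def gaussian_kernel(
    distance_km: float,
    cell_size_km: float = 1.0,
    sigma_divisor: float = DEFAULT_SIGMA_DIVISOR,
) -> np.ndarray:
    """Odd-sided square Gaussian kernel with unit sum.

    sigma = distance_km / sigma_divisor, truncated at radius ceil(3*sigma)
    cells; a distance below half a cell collapses to the 1x1 identity
    kernel (no spreading). Unit sum means convolution redistributes rather
    than inflates intensity.
    """
    if distance_km < 0:
        raise ValueError("pressure distance must be non-negative")
    if cell_size_km <= 0:
        raise ValueError("cell size must be positive")
    if distance_km < cell_size_km / 2:
        return np.ones((1, 1))
    sigma_cells = (distance_km / sigma_divisor) / cell_size_km
    radius = int(np.ceil(3 * sigma_cells))
    radius = max(radius, 1)
    offsets = np.arange(-radius, radius + 1)
    g = np.exp(-0.5 * (offsets / sigma_cells) ** 2)
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


@lru_cache(maxsize=64)
def _warn_oversized_kernel(kernel_shape: tuple, grid_shape: tuple) -> None:
    # deduplicated: a Monte Carlo batch would otherwise repeat this per run
    logger.warning(
        "kernel %s larger than twice the grid %s; proceeding", kernel_shape, grid_shape
    )


def convolve_use(use_layer: Layer, kernel: np.ndarray) -> Layer:
    """Spread a use footprint into a pressure-intensity layer.

    Discrete 2D convolution with zero padding beyond the domain (an open
    boundary: intensity may leak out), then rescaled to [0, 1] by its
    maximum so the response function's domain is well defined.
    """
    if kernel.shape[0] > 2 * use_layer.grid.n_rows or kernel.shape[1] > 2 * use_layer.grid.n_cols:
        _warn_oversized_kernel(kernel.shape, use_layer.grid.shape)
    vals = np.where(use_layer.grid.valid_mask, use_layer.values, 0.0)
    if kernel.shape == (1, 1):
        out = vals * kernel[0, 0]
    else:
        out = signal.oaconvolve(vals, kernel, mode="same")
    out = np.clip(out, 0.0, None)
    vmax = out.max()
    if vmax > 0:
        out = out / vmax
    return use_layer.copy_with(out, role="pressure_intensity")


def response_transform(x: np.ndarray | float, rp: ResponseParams) -> np.ndarray | float:
    """Apply the ecosystem response rf to a pressure intensity in [0, 1].

    rf(x) = (1-nr)*x + nr*L(x) with L a logistic with inflection at sr,
    affinely renormalized so L(0) = 0 and L(1) = 1. Continuous,
    non-decreasing, rf(0) = 0 and rf(1) = 1 for every parameter choice.
    """
    arr = np.asarray(x, dtype=float)
    if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
        raise ValueError("response_transform input must lie in [0,1]")
    arr = np.clip(arr, 0.0, 1.0)
    if rp.nr == 0:
        out = arr
    else:
        s = rp.steepness
        raw = 1.0 / (1.0 + np.exp(-s * (arr - rp.sr)))
        raw0 = 1.0 / (1.0 + np.exp(s * rp.sr))
        raw1 = 1.0 / (1.0 + np.exp(-s * (1.0 - rp.sr)))
        logistic = (raw - raw0) / (raw1 - raw0)
        out = (1.0 - rp.nr) * arr + rp.nr * logistic
    return float(out) if np.isscalar(x) else out


def impact_layer(
    ds: CIDataset,
    rec: SensitivityRecord,
    rp: ResponseParams = ResponseParams(),
    sigma_divisor: float = DEFAULT_SIGMA_DIVISOR,
    score: float | None = None,
    distance_km: float | None = None,
) -> Layer:
    """Impact of one (U, P, E) relationship: s * rf(spread pressure) * d(E).

    ``score`` / ``distance_km`` override the elicited record values; the
    uncertainty analysis uses them to inject sampled errors.
    """
    use = ds.uses[rec.use_id]
    env = ds.envs[rec.env_id]
    s = rec.score if score is None else score
    d_km = rec.distance_km if distance_km is None else distance_km
    kernel = gaussian_kernel(d_km, ds.grid.cell_size_km, sigma_divisor)
    pressure = convolve_use(use, kernel)
    response = response_transform(pressure.values, rp)
    vals = s * response * env.values
    vals[~ds.grid.valid_mask] = 0.0
    return Layer(ds.grid, vals, role="impact")


def combine_impacts(stack: np.ndarray | list, cp: CombinationParams) -> np.ndarray:
    """Blend a stack of impact layers: (1-mscf)*sum + mscf*max, cell-wise."""
    if isinstance(stack, list):
        stack = np.stack([s.values if isinstance(s, Layer) else s for s in stack]) \
            if stack else np.zeros((0, 1, 1))
    if stack.shape[0] == 0:
        logger.warning("combine_impacts: empty stack, returning zero map")
        return np.zeros(stack.shape[1:])
    total = stack.sum(axis=0)
    dominant = stack.max(axis=0)
    return (1.0 - cp.mscf) * total + cp.mscf * dominant


def compute_ci(
    ds: CIDataset,
    rp: ResponseParams = ResponseParams(),
    cp: CombinationParams = CombinationParams(),
    sigma_divisor: float = DEFAULT_SIGMA_DIVISOR,
    scores: np.ndarray | None = None,
    distances: np.ndarray | None = None,
) -> CIResult:
    """Run the CI model: materialize all impact layers and combine them.

    ``scores``/``distances`` optionally override the elicited values
    per triple (aligned with ``ds.sensitivities``). The baseline run is the
    default (nr=0, mscf=0).
    """
    ds.validate()
    n = len(ds.sensitivities)
    stack = np.zeros((n, ds.grid.n_rows, ds.grid.n_cols))
    for t, rec in enumerate(ds.sensitivities):
        stack[t] = impact_layer(
            ds, rec, rp, sigma_divisor,
            score=None if scores is None else float(scores[t]),
            distance_km=None if distances is None else float(distances[t]),
        ).values
    ci_vals = combine_impacts(stack, cp) if n else np.zeros(ds.grid.shape)
    ci_vals[~ds.grid.valid_mask] = 0.0
    valid = ds.grid.valid_mask
    totals = stack[:, valid].sum(axis=1) if n else np.zeros(0)
    return CIResult(
        ci_map=Layer(ds.grid, ci_vals, role="index"),
        impact_stack=stack,
        triples=list(ds.sensitivities),
        triple_totals=totals,
        response=rp,
        combination=cp,
    )


def contribution_stats(
    res: CIResult, ds: CIDataset, footprint_eps_frac: float = 1e-6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-use and per-component contribution tables.

    For each use: presence% (cells with nonzero use intensity among valid
    cells), impacted% (cells where any of its impact layers exceeds the
    footprint threshold), score% (its share of the summed impact). For each
    component: presence%, impacted% among its presence cells, score%. A
    component with impacted% = 100 is impacted across its entire coverage.
    """
    valid = ds.grid.valid_mask
    n_valid = valid.sum()
    eps = footprint_eps_frac * (res.impact_stack.max() if res.impact_stack.size else 1.0)
    grand_total = res.triple_totals.sum()
    if grand_total == 0:
        logger.warning("contribution_stats: total CI is 0; score%% reported as 0")

    def _share(total: float) -> float:
        return 100.0 * total / grand_total if grand_total > 0 else 0.0

    use_rows = []
    for uid, layer in ds.uses.items():
        idx = [t for t, rec in enumerate(res.triples) if rec.use_id == uid]
        presence = 100.0 * ((layer.values > 0) & valid).sum() / n_valid
        if idx:
            impacted_cells = (res.impact_stack[idx] > eps).any(axis=0) & valid
            impacted = 100.0 * impacted_cells.sum() / n_valid
            score_pct = _share(res.triple_totals[idx].sum())
        else:
            impacted, score_pct = 0.0, 0.0
        use_rows.append({"use_id": uid, "presence_pct": presence,
                         "impacted_pct": impacted, "score_pct": score_pct})

    env_rows = []
    for eid, layer in ds.envs.items():
        idx = [t for t, rec in enumerate(res.triples) if rec.env_id == eid]
        present = (layer.values > 0) & valid
        presence = 100.0 * present.sum() / n_valid
        if idx and present.any():
            impacted_cells = (res.impact_stack[idx] > eps).any(axis=0) & present
            impacted = 100.0 * impacted_cells.sum() / present.sum()
            score_pct = _share(res.triple_totals[idx].sum())
        else:
            impacted, score_pct = 0.0, 0.0
        env_rows.append({"env_id": eid, "presence_pct": presence,
                         "impacted_pct": impacted, "score_pct": score_pct})

    return pd.DataFrame(use_rows), pd.DataFrame(env_rows)


def rank_triples(res: CIResult, m: int = 60) -> list[tuple[SensitivityRecord, float]]:
    """Top-m (U, P, E) relationships by summed impact contribution.

    Ties are broken by (use_id, pressure_id, env_id) lexicographic order.
    The default m = 60 matches the factor-space construction for the
    sensitivity analysis, which perturbs the 60 most weighted triples of
    the baseline run.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    order = sorted(
        range(len(res.triples)),
        key=lambda t: (-res.triple_totals[t], res.triples[t].triple),
    )
    return [(res.triples[t], float(res.triple_totals[t])) for t in order[:m]]
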