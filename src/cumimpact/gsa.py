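"""Global uncertainty (UA) and sensitivity (SA) analysis of the CI model.

Four factor groups drive the analysis:

* **SC** — sensitivity-score errors: one beta-distributed factor per
  top-ranked (use, pressure, component) triple, mode at the elicited score,
  spread shrinking with expert confidence;
* **D** — pressure-distance errors: likewise beta-distributed on [0, 50] km;
* **MSCF** — the multi-stressor combination factor, uniform on [0, 1];
* **RF** — the response-function parameters, NR ~ U(0, 1) and
  SR ~ U(0.3, 0.7).

Sampling follows the Saltelli radial design at cost N(2k+2) runs for k
groups (k = 4, so N = 1500 gives 15,000 runs), on a scrambled Sobol'
quasi-random sequence with each marginal obtained through its inverse CDF.
Groups are permuted together (block columns), yielding group-level indices.

Per grid cell, variance shares are estimated with the standard estimators:
first-order S1 (Saltelli 2010), total-effect ST (Jansen), and closed
second-order S2 (Saltelli 2002). The UA summarises the run ensemble per
cell by its coefficient of variation and by exceedance frequencies — how
often a cell ranks among each run's most impacted 25%/10% (above the
75th/90th percentile) or least impacted (below the 25th/10th).

The target function is the CI score of each run rescaled to 0-1 by the
run's domain maximum, so the analysis addresses relative spatial pattern
rather than absolute magnitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .ci import (
    CIResult,
    CombinationParams,
    ResponseParams,
    combine_impacts,
    convolve_use,
    gaussian_kernel,
    rank_triples,
    response_transform,
)
from .datamodel import CIDataset, Layer, MAX_DISTANCE_KM

logger = logging.getLogger(__name__)

GROUP_NAMES = ("SC", "D", "MSCF", "RF")

#: concentration scale of the confidence -> beta mapping: kappa = 2 + c*K.
#: c = 0 gives the uniform distribution (no information), c = 1 a
#: concentration of 20 (sd ~ 0.1 around a central mode).
DEFAULT_KAPPA_SCALE = 18.0


def beta_from_mode_confidence(
    m: float, c: float, K: float = DEFAULT_KAPPA_SCALE
) -> tuple[float, float]:
    """Beta(alpha, beta) shape parameters from a modal value and a confidence.

    alpha = 1 + m*(kappa-2), beta = 1 + (1-m)*(kappa-2) with
    kappa = 2 + c*K. The distribution's mode equals ``m`` whenever
    kappa > 2, and its variance decreases strictly with confidence;
    c = 0 degenerates to the uniform on [0, 1].
    """
    if not 0.0 <= m <= 1.0 or not 0.0 <= c <= 1.0:
        raise ValueError("mode and confidence must lie in [0,1]")
    if K <= 0:
        raise ValueError("concentration scale K must be positive")
    kappa = 2.0 + c * K
    return 1.0 + m * (kappa - 2.0), 1.0 + (1.0 - m) * (kappa - 2.0)


@dataclass(frozen=True)
class Factor:
    """One scalar factor: a name and an inverse CDF over the unit interval."""

    name: str
    ppf: Callable[[np.ndarray], np.ndarray]

    @staticmethod
    def uniform(name: str, lo: float, hi: float) -> "Factor":
        return Factor(name, lambda u, lo=lo, hi=hi: lo + (hi - lo) * u)

    @staticmethod
    def constant(name: str, value: float) -> "Factor":
        return Factor(name, lambda u, v=value: np.full_like(np.asarray(u, float), v))

    @staticmethod
    def beta(name: str, mode: float, confidence: float,
             scale: float = 1.0, K: float = DEFAULT_KAPPA_SCALE) -> "Factor":
        a, b = beta_from_mode_confidence(mode, confidence, K)
        return Factor(name, lambda u, a=a, b=b, s=scale: s * stats.beta.ppf(u, a, b))


@dataclass(frozen=True)
class FactorGroup:
    """A named block of factors sampled (and permuted) together."""

    name: str
    factors: tuple[Factor, ...]

    @property
    def dim(self) -> int:
        return len(self.factors)


@dataclass
class FactorSpace:
    """The factor groups of one analysis plus the triple bookkeeping."""

    groups: list[FactorGroup]
    top_idx: list[int] = field(default_factory=list)  # into ds.sensitivities

    @property
    def dims(self) -> int:
        return sum(g.dim for g in self.groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    def group_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for g in self.groups:
            out[g.name] = slice(start, start + g.dim)
            start += g.dim
        return out

    def transform(self, unit: np.ndarray) -> np.ndarray:
        """Map unit-hypercube samples (n, dims) through each factor's inverse CDF."""
        values = np.empty_like(unit, dtype=float)
        col = 0
        for g in self.groups:
            for f in g.factors:
                values[:, col] = f.ppf(unit[:, col])
                col += 1
        return values


@dataclass(frozen=True)
class SobolPlan:
    """Saltelli design size: N base samples over k groups, N(2k+2) runs."""

    n_base: int
    k: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_base < 2 or self.k < 1:
            raise ValueError("need n_base >= 2 and k >= 1")

    @property
    def total_runs(self) -> int:
        return self.n_base * (2 * self.k + 2)


@dataclass
class SampleMatrix:
    """The realized run matrix with its block layout.

    Rows are ordered [A, B, AB_1..AB_k, BA_1..BA_k], each block of
    ``plan.n_base`` rows; AB_g is A with group g's columns taken from B.
    """

    values: np.ndarray  # (total_runs, dims)
    plan: SobolPlan
    space: FactorSpace


def build_factor_space(
    ds: CIDataset,
    baseline: CIResult,
    top_m: int = 60,
    K: float = DEFAULT_KAPPA_SCALE,
    sample_groups: Sequence[str] = GROUP_NAMES,
) -> FactorSpace:
    """Factor space for the four-group analysis of a dataset.

    SC and D hold one beta factor per top-``top_m`` triple of the baseline
    run (triples outside the top keep their elicited point values inside
    the model); MSCF and RF follow their fixed uniform ranges. Groups not
    named in ``sample_groups`` are pinned at their baseline values
    (degenerate distributions) — used for factor-recovery experiments.
    """
    ranked = rank_triples(baseline, m=min(top_m, len(baseline.triples)))
    if top_m > len(baseline.triples):
        logger.info(
            "top_m=%d exceeds %d triples; using all", top_m, len(baseline.triples)
        )
    triple_index = {rec.triple: i for i, rec in enumerate(ds.sensitivities)}
    top_idx = [triple_index[rec.triple] for rec, _ in ranked]

    def _beta_or_const(name, mode, conf, scale, value, active):
        if active:
            return Factor.beta(name, mode, conf, scale=scale, K=K)
        return Factor.constant(name, value)

    sc = tuple(
        _beta_or_const(f"SC:{'|'.join(rec.triple)}", rec.score, rec.confidence,
                       1.0, rec.score, "SC" in sample_groups)
        for rec, _ in ranked
    )
    d = tuple(
        _beta_or_const(f"D:{'|'.join(rec.triple)}", rec.distance_km / MAX_DISTANCE_KM,
                       rec.confidence, MAX_DISTANCE_KM, rec.distance_km,
                       "D" in sample_groups)
        for rec, _ in ranked
    )
    mscf = (
        Factor.uniform("MSCF", 0.0, 1.0)
        if "MSCF" in sample_groups
        else Factor.constant("MSCF", baseline.combination.mscf),
    )
    rf = (
        Factor.uniform("NR", 0.0, 1.0)
        if "RF" in sample_groups
        else Factor.constant("NR", baseline.response.nr),
        Factor.uniform("SR", 0.3, 0.7)
        if "RF" in sample_groups
        else Factor.constant("SR", baseline.response.sr),
    )
    groups = [
        FactorGroup("SC", sc),
        FactorGroup("D", d),
        FactorGroup("MSCF", mscf),
        FactorGroup("RF", rf),
    ]
    return FactorSpace(groups, top_idx)


def saltelli_sample(space: FactorSpace, plan: SobolPlan) -> SampleMatrix:
    """Generate the Saltelli radial design on a scrambled Sobol' sequence.

    Draws a 2*dims quasi-random base, splits it into matrices A and B, and
    builds the AB/BA radial blocks per group; the same seed always yields
    the same matrix.
    """
    if space.dims == 0:
        raise ValueError("factor space has no dimensions")
    if plan.k != space.k:
        raise ValueError(f"plan has k={plan.k} but space has {space.k} groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-2 N
        sampler = qmc.Sobol(d=2 * space.dims, scramble=True, seed=plan.seed)
        base = sampler.random(plan.n_base)
    A, B = base[:, : space.dims], base[:, space.dims:]
    blocks = [A, B]
    slices = list(space.group_slices().values())
    for sl in slices:  # AB_g: A with group g from B
        ab = A.copy()
        ab[:, sl] = B[:, sl]
        blocks.append(ab)
    for sl in slices:  # BA_g: B with group g from A
        ba = B.copy()
        ba[:, sl] = A[:, sl]
        blocks.append(ba)
    unit = np.vstack(blocks)
    return SampleMatrix(space.transform(unit), plan, space)


# ---------------------------------------------------------------------------
# model evaluation


def run_model_batch(
    ds: CIDataset,
    sample: SampleMatrix,
    sigma_divisor: float | None = None,
    progress: bool = False,
) -> np.ndarray:
    """Evaluate the CI model on every design row.

    Returns (total_runs, n_valid_cells) with each run's map divided by its
    own domain maximum (the relative-CI target function). Rows are
    independent; pressure layers for unperturbed (use, distance) pairs are
    cached across runs.
    """
    from .ci import DEFAULT_SIGMA_DIVISOR

    sigma_divisor = sigma_divisor or DEFAULT_SIGMA_DIVISOR
    space = sample.space
    sl = space.group_slices()
    n_triples = len(ds.sensitivities)
    top_idx = space.top_idx
    valid = ds.grid.valid_mask

    base_scores = np.array([r.score for r in ds.sensitivities])
    base_dist = np.array([r.distance_km for r in ds.sensitivities])
    envs = np.stack([ds.envs[r.env_id].values for r in ds.sensitivities])

    pressure_cache: dict[tuple[str, float], np.ndarray] = {}

    def pressure(use_id: str, dist: float) -> np.ndarray:
        key = (use_id, round(float(dist), 9))
        if key not in pressure_cache:
            if len(pressure_cache) > 512:
                pressure_cache.clear()
            kernel = gaussian_kernel(dist, ds.grid.cell_size_km, sigma_divisor)
            pressure_cache[key] = convolve_use(ds.uses[use_id], kernel).values
        return pressure_cache[key]

    rows = sample.values
    outputs = np.zeros((rows.shape[0], int(valid.sum())))
    for r in range(rows.shape[0]):
        row = rows[r]
        scores = base_scores.copy()
        dists = base_dist.copy()
        scores[top_idx] = row[sl["SC"]]
        dists[top_idx] = row[sl["D"]]
        mscf = float(row[sl["MSCF"]][0])
        nr, sr = row[sl["RF"]]
        rp = ResponseParams(float(np.clip(nr, 0, 1)), float(np.clip(sr, 0.3, 0.7)))
        stack = np.empty((n_triples,) + ds.grid.shape)
        for t, rec in enumerate(ds.sensitivities):
            p = pressure(rec.use_id, dists[t])
            stack[t] = scores[t] * response_transform(p, rp) * envs[t]
        ci = combine_impacts(stack, CombinationParams(mscf))
        out = ci[valid]
        vmax = out.max()
        if vmax > 0:
            out = out / vmax
        else:
            logger.info("run %d produced an all-zero CI map", r)
        outputs[r] = out
        if progress and r % 500 == 0:
            logger.info("run %d / %d", r, rows.shape[0])
    return outputs


# ---------------------------------------------------------------------------
# estimators and summaries


@dataclass
class SAResult:
    s1: dict[str, np.ndarray]       # per-group per-cell first-order index
    st: dict[str, np.ndarray]       # per-group per-cell total-effect index
    s2_pairs: pd.DataFrame          # mean second-order index per group pair
    means: pd.DataFrame             # domain means of S1, ST per group (percent)
    s1_sum: np.ndarray              # per-cell sum of first-order indices


def sobol_indices(outputs: np.ndarray, plan: SobolPlan,
                  group_names: Sequence[str] = GROUP_NAMES) -> SAResult:
    """Per-cell Sobol' indices from a Saltelli-design output matrix.

    ``outputs`` is (N(2k+2), n_cells) in the block order produced by
    :func:`saltelli_sample`. S1 uses the Saltelli-2010 first-order
    estimator, ST the Jansen estimator, S2 the closed Saltelli-2002
    estimator. Cells with zero output variance are NaN. Negative estimates
    (Monte Carlo noise) are reported as-is.
    """
    N, k = plan.n_base, plan.k
    if outputs.shape[0] != plan.total_runs:
        raise ValueError(
            f"outputs has {outputs.shape[0]} rows, plan expects {plan.total_runs}"
        )
    names = list(group_names)[:k]
    fA = outputs[:N]
    fB = outputs[N: 2 * N]
    fAB = [outputs[(2 + g) * N: (3 + g) * N] for g in range(k)]
    fBA = [outputs[(2 + k + g) * N: (3 + k + g) * N] for g in range(k)]

    V = np.var(np.concatenate([fA, fB]), axis=0)
    ok = V > 0
    Vsafe = np.where(ok, V, 1.0)

    s1, st = {}, {}
    for g, name in enumerate(names):
        s1_g = np.mean(fB * (fAB[g] - fA), axis=0) / Vsafe
        st_g = 0.5 * np.mean((fA - fAB[g]) ** 2, axis=0) / Vsafe
        s1[name] = np.where(ok, s1_g, np.nan)
        st[name] = np.where(ok, st_g, np.nan)

    pair_rows = []
    for i in range(k):
        for j in range(i + 1, k):
            vij = np.mean(fBA[i] * fAB[j] - fA * fB, axis=0) / Vsafe
            s2_ij = vij - s1[names[i]] - s1[names[j]]
            pair_rows.append({
                "group_i": names[i], "group_j": names[j],
                "s2_mean_pct": 100.0 * np.nanmean(np.where(ok, s2_ij, np.nan)),
            })
    s2_pairs = pd.DataFrame(pair_rows)

    means = pd.DataFrame({
        "group": names,
        "s1_mean_pct": [100.0 * np.nanmean(s1[n]) for n in names],
        "st_mean_pct": [100.0 * np.nanmean(st[n]) for n in names],
    })
    s1_sum = np.sum([s1[n] for n in names], axis=0)
    return SAResult(s1, st, s2_pairs, means, s1_sum)


@dataclass
class UAResult:
    mean: np.ndarray
    cv: np.ndarray
    freq_most: dict[int, np.ndarray]   # threshold pct -> per-cell frequency
    freq_least: dict[int, np.ndarray]


def ua_summaries(outputs: np.ndarray,
                 thresholds: Sequence[int] = (25, 10)) -> UAResult:
    """Uncertainty summaries of the run ensemble.

    CV is the population standard deviation over runs divided by the mean
    (NaN where the mean is zero). For each run, cells strictly above the
    run's (100-t)th percentile over valid cells count as "most impacted",
    cells strictly below the t-th percentile as "least impacted"; the
    frequency maps give the fraction of runs in which each cell was so
    flagged. CV and all frequencies are invariant under a positive
    rescaling of the whole ensemble.
    """
    if outputs.shape[0] < 2:
        raise ValueError("need at least 2 runs for ensemble summaries")
    mean = outputs.mean(axis=0)
    std = outputs.std(axis=0)  # population std
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, std / np.where(mean > 0, mean, 1.0), np.nan)
    freq_most, freq_least = {}, {}
    for t in thresholds:
        hi = np.percentile(outputs, 100 - t, axis=1, method="linear")
        lo = np.percentile(outputs, t, axis=1, method="linear")
        freq_most[t] = (outputs > hi[:, None]).mean(axis=0)
        freq_least[t] = (outputs < lo[:, None]).mean(axis=0)
    return UAResult(mean, cv, freq_most, freq_least)


def cells_to_layer(values: np.ndarray, grid, role: str = "index") -> Layer:
    """Place a valid-cell vector back on the grid (nodata cells NaN)."""
    out = np.full(grid.shape, np.nan)
    out[grid.valid_mask] = values
    return Layer(grid, out, role=role)


def frequency_area_curve(freq: np.ndarray,
                         levels: np.ndarray | None = None) -> pd.DataFrame:
    """Share of valid cells flagged in at least each fraction of runs."""
    levels = np.linspace(0.0, 1.0, 21) if levels is None else np.asarray(levels)
    finite = freq[np.isfinite(freq)]
    rows = [
        {"min_run_fraction": float(lv),
         "area_pct": 100.0 * (finite >= lv).mean() if finite.size else float("nan")}
        for lv in levels
    ]
    return pd.DataFrame(rows)
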