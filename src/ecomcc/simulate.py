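"""Synthetic lagoon-style community time series with known ground truth.

The generator emulates the statistical structure of replicated benthic
monitoring data: a modest taxon pool whose expected abundances span several
orders of magnitude, plot-level spatial effects, year-level temporal effects
with a plot x year interaction (all multiplicative on the expectation, i.e.
additive on the log scale), overdispersed counts (gamma-Poisson / negative
binomial), and a replicated design template of 3 plots x 5 times x
4 replicates per plot-time.  Optional press or pulse disturbances perturb a
seeded subset of taxa so detection power can be studied against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import rng_for
from .community import CommunityMatrix

__all__ = [
    "Disturbance",
    "SimulationConfig",
    "GroundTruth",
    "simulate_community",
    "inject_disturbance",
]


@dataclass(frozen=True)
class Disturbance:
    """A press or pulse perturbation of expected abundances.

    pulse: at time index ``time`` only, the expectations of a seeded fraction
    of taxa are multiplied by ``multiplier``.
    press: from time index ``start`` onward the affected taxa follow a
    compounding per-step log-scale trend: factor exp(trend * steps_since_start)
    with steps_since_start = 1 at ``start``.
    """

    kind: str                      # "pulse" | "press"
    time: int | None = None        # pulse time index (0-based)
    start: int | None = None       # press start index (0-based)
    multiplier: float = 1.0        # pulse multiplier
    trend: float = 0.0             # press per-step log trend
    affected_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("pulse", "press"):
            raise ValueError(f"unknown disturbance kind {self.kind!r}")
        if self.kind == "pulse":
            if self.time is None:
                raise ValueError("pulse disturbance needs a time index")
            if self.multiplier <= 0:
                raise ValueError("pulse multiplier must be > 0")
        if self.kind == "press" and self.start is None:
            raise ValueError("press disturbance needs a start index")
        if not (0.0 < self.affected_fraction <= 1.0):
            raise ValueError("affected fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design template and effect sizes for the generator.

    Defaults mirror the repeated lagoon sampling design: one site with
    3 plots x 5 times x 4 replicates and 30 taxa whose base expectations span
    3 orders of magnitude.  Effect standard deviations act on the
    log-abundance scale per (level, taxon); ``overdispersion`` is the
    negative-binomial shape k (variance mu + mu^2/k; None = Poisson limit).
    """

    n_sites: int = 1
    n_plots: int = 3
    n_times: int = 5
    n_replicates: int = 4
    n_taxa: int = 30
    dominance_span: float = 3.0
    base_max: float = 200.0
    plot_effect_sd: float = 0.5
    time_effect_sd: float = 0.3
    interaction_effect_sd: float = 0.3
    overdispersion: float | None = 2.0
    disturbance: Disturbance | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_plots", "n_times", "n_replicates", "n_taxa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("plot_effect_sd", "time_effect_sd", "interaction_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dominance_span < 0:
            raise ValueError("dominance span must be >= 0")
        if self.base_max <= 0:
            raise ValueError("base_max must be > 0")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion k must be > 0 (or None for Poisson)")
        if self.disturbance is not None:
            d = self.disturbance
            if d.kind == "pulse" and not (0 <= d.time < self.n_times):
                raise ValueError(f"pulse time {d.time} outside the series (0..{self.n_times - 1})")
            if d.kind == "press" and not (0 <= d.start < self.n_times):
                raise ValueError(f"press start {d.start} outside the series")


@dataclass
class GroundTruth:
    """What the generator actually did: per-cell expected abundances (after any
    disturbance), the realized effect draws, and the disturbance incidence."""

    expected: pd.DataFrame               # samples x taxa expectations
    base_abundance: np.ndarray           # per-taxon baseline expectation
    plot_effects: np.ndarray             # (site, plot, taxon)
    time_effects: np.ndarray             # (site, time, taxon)
    interaction_effects: np.ndarray      # (site, plot, time, taxon)
    disturbed: pd.DataFrame              # samples x taxa boolean incidence
    affected_taxa: list
    config: SimulationConfig


def _labels(cfg: SimulationConfig):
    sites = [f"site-{i + 1}" for i in range(cfg.n_sites)]
    plots = [f"plot-{i + 1}" for i in range(cfg.n_plots)]
    times = [f"{2006 + i}" for i in range(cfg.n_times)]
    reps = [f"r{i + 1}" for i in range(cfg.n_replicates)]
    taxa = [f"taxon-{i + 1:02d}" for i in range(cfg.n_taxa)]
    return sites, plots, times, reps, taxa


def _disturbance_factor(cfg: SimulationConfig, affected_mask: np.ndarray) -> np.ndarray:
    """(time, taxon) multiplicative factor implied by the disturbance spec."""
    factor = np.ones((cfg.n_times, cfg.n_taxa))
    d = cfg.disturbance
    if d is None:
        return factor
    if d.kind == "pulse":
        factor[d.time, affected_mask] = d.multiplier
    else:
        for t in range(d.start, cfg.n_times):
            steps = t - d.start + 1
            factor[t, affected_mask] = np.exp(d.trend * steps)
    return factor


def simulate_community(config: SimulationConfig) -> tuple[CommunityMatrix, GroundTruth]:
    """Draw one community matrix (and its ground truth) from the model.

    Taxon base expectations are log-spaced across the dominance span (the
    most and least abundant taxa differ by exactly 10**span).  Each cell's
    expectation is base * exp(plot + time + interaction effects) * disturbance
    factor, with effects drawn once per (site, level, taxon) and shared by all
    replicates; counts are negative binomial around the expectation.
    Deterministic under the seed.
    """
    cfg = config
    sites, plots, times, reps, taxa = _labels(cfg)
    if cfg.n_taxa == 1:
        base = np.array([cfg.base_max])
    else:
        base = cfg.base_max * 10.0 ** (
            -np.linspace(0.0, cfg.dominance_span, cfg.n_taxa)
        )

    rng_fx = rng_for(cfg.seed, "effects")
    plot_eff = rng_fx.normal(0.0, cfg.plot_effect_sd, size=(cfg.n_sites, cfg.n_plots, cfg.n_taxa))
    time_eff = rng_fx.normal(0.0, cfg.time_effect_sd, size=(cfg.n_sites, cfg.n_times, cfg.n_taxa))
    inter_eff = rng_fx.normal(
        0.0, cfg.interaction_effect_sd, size=(cfg.n_sites, cfg.n_plots, cfg.n_times, cfg.n_taxa)
    )

    rng_dist = rng_for(cfg.seed, "disturbance")
    if cfg.disturbance is not None:
        n_aff = max(1, int(round(cfg.disturbance.affected_fraction * cfg.n_taxa)))
        affected_idx = np.sort(rng_dist.choice(cfg.n_taxa, size=n_aff, replace=False))
    else:
        affected_idx = np.array([], dtype=int)
    affected_mask = np.zeros(cfg.n_taxa, dtype=bool)
    affected_mask[affected_idx] = True
    factor = _disturbance_factor(cfg, affected_mask)

    rng_counts = rng_for(cfg.seed, "counts")
    rows, meta, ids = [], [], []
    exp_rows, dist_rows = [], []
    for si, site in enumerate(sites):
        for pi, plot in enumerate(plots):
            for ti, time in enumerate(times):
                mu = (
                    base
                    * np.exp(plot_eff[si, pi] + time_eff[si, ti] + inter_eff[si, pi, ti])
                    * factor[ti]
                )
                for rep in reps:
                    counts = _draw_counts(rng_counts, mu, cfg.overdispersion)
                    rows.append(counts)
                    exp_rows.append(mu.copy())
                    dist_rows.append(affected_mask & (factor[ti] != 1.0))
                    ids.append(f"{site}_{plot}_{time}_{rep}")
                    meta.append(dict(site=site, plot=plot, time=time, replicate=rep))

    ab = pd.DataFrame(np.array(rows, dtype=float), index=ids, columns=taxa)
    md = pd.DataFrame(meta, index=ids)
    M = CommunityMatrix(ab, md)
    truth = GroundTruth(
        expected=pd.DataFrame(np.array(exp_rows), index=ids, columns=taxa),
        base_abundance=base,
        plot_effects=plot_eff,
        time_effects=time_eff,
        interaction_effects=inter_eff,
        disturbed=pd.DataFrame(np.array(dist_rows), index=ids, columns=taxa),
        affected_taxa=[taxa[i] for i in affected_idx],
        config=cfg,
    )
    return M, truth


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, k: float | None) -> np.ndarray:
    if k is None:
        return rng.poisson(mu).astype(float)
    # gamma-Poisson mixture: var = mu + mu^2 / k
    lam = rng.gamma(shape=k, scale=mu / k)
    return rng.poisson(lam).astype(float)


def inject_disturbance(
    M: CommunityMatrix, truth: GroundTruth, disturbance: Disturbance
) -> tuple[CommunityMatrix, GroundTruth]:
    """Apply a disturbance to an already-simulated matrix.

    Expectations of the affected cells are modified per the disturbance spec
    and only those cells' counts are redrawn (from a stream derived from the
    original seed), so an ineffective disturbance (multiplier 1, trend 0)
    returns a byte-identical matrix.
    """
    cfg = replace(truth.config, disturbance=disturbance)  # validates indices
    sites, plots, times, reps, taxa = _labels(truth.config)

    rng_dist = rng_for(truth.config.seed, "inject", disturbance.kind)
    n_aff = max(1, int(round(disturbance.affected_fraction * cfg.n_taxa)))
    affected_idx = np.sort(rng_dist.choice(cfg.n_taxa, size=n_aff, replace=False))
    affected_mask = np.zeros(cfg.n_taxa, dtype=bool)
    affected_mask[affected_idx] = True
    factor = _disturbance_factor(cfg, affected_mask)

    ab = M.abundance.copy()
    expected = truth.expected.copy()
    disturbed = truth.disturbed.copy()
    rng_counts = rng_for(truth.config.seed, "inject-counts")
    time_index = {t: i for i, t in enumerate(times)}
    for sid in M.sample_ids:
        ti = time_index[str(M.metadata.loc[sid, "time"])]
        row_factor = factor[ti]
        changed = row_factor != 1.0
        if not changed.any():
            continue
        mu_new = expected.loc[sid].to_numpy(dtype=float) * row_factor
        redraw = _draw_counts(rng_counts, mu_new[changed], truth.config.overdispersion)
        new_row = ab.loc[sid].to_numpy(dtype=float)
        new_row[changed] = redraw
        ab.loc[sid] = new_row
        expected.loc[sid] = mu_new
        disturbed.loc[sid] = disturbed.loc[sid].to_numpy(dtype=bool) | changed
    M_out = CommunityMatrix(ab, M.metadata.copy())
    truth_out = GroundTruth(
        expected=expected,
        base_abundance=truth.base_abundance,
        plot_effects=truth.plot_effects,
        time_effects=truth.time_effects,
        interaction_effects=truth.interaction_effects,
        disturbed=disturbed,
        affected_taxa=[taxa[i] for i in affected_idx],
        config=cfg,
    )
    return M_out, truth_out
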