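"""Multivariate control charts for community time series.

A control chart tracks, for every sampling plot, the Bray-Curtis-space
distance of the plot's community at time t from a reference centroid:

* **baseline** chart — reference = centroid of the first ``m`` sampling times
  of that plot (default m = 2); sensitive to gradual "press" change;
* **sequential** chart — reference at time t = centroid of all times up to
  and including t-1; the reference moves with the data, so the chart is
  sensitive to one-off "pulse" change.

Statistical control limits are the means over B bootstrap iterations of the
50th and 95th percentiles of deviations recomputed after resampling each
plot's time series with replacement.  For the baseline chart the bootstrap
percentile distribution is time-invariant, so deviations are pooled over all
charted times; for the sequential chart the percentiles are time-point
specific.  A deviation above the 95th-percentile limit is flagged
"out of control".

Each (plot, time) observation is the set of its replicate samples; its
community is the centroid of the replicates in the (signed) PCoA embedding,
and all distances follow the centroid identities of
:mod:`ecomcc.geometry`.  Internally the bootstrap uses block sums of squared
dissimilarities between (plot, time) cells, which is algebraically identical
to recomputing ``centroid_sq_distance`` on unions of replicate sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rng_for, spawn_seed, time_sort_key
from .community import CommunityMatrix, DissimilarityMatrix
from .geometry import centroid_sq_distance

__all__ = [
    "ChartSpec",
    "ControlChart",
    "ControlLimits",
    "plot_time_points",
    "chart_baseline",
    "chart_sequential",
    "bootstrap_limits",
    "flag_out_of_control",
    "assign_pseudo_plots",
    "chart_table",
    "plot_control_charts",
]


@dataclass
class ChartSpec:
    """Parameters of a control-chart analysis."""

    chart_type: str = "baseline"          # "baseline" | "sequential"
    baseline_size: int = 2                # m, number of initial times in the baseline
    percentiles: tuple = (50.0, 95.0)
    n_boot: int = 10000                   # B, bootstrap iterations for the limits
    seed: int = 0
    replicate_level: bool = False         # chart every replicate, not the centroid

    def __post_init__(self) -> None:
        if self.chart_type not in ("baseline", "sequential"):
            raise ValueError(f"unknown chart type {self.chart_type!r}")
        if self.baseline_size < 1:
            raise ValueError("baseline size m must be >= 1")
        if self.n_boot < 1:
            raise ValueError("bootstrap sample count B must be >= 1")
        if not all(0.0 < p < 100.0 for p in self.percentiles):
            raise ValueError("percentiles must lie in (0, 100)")


@dataclass
class PlotSeries:
    """One plot's ordered time series of replicate-sample index sets."""

    plot: tuple                       # (site, plot) key
    times: list                       # ordered time labels present for this plot
    cells: list                       # list of int arrays, replicate indices per time


@dataclass
class ControlChart:
    """Per-plot deviation series for one chart type.

    ``deviations`` maps (site, plot) -> (times, d_t array); ``provenance``
    records which sample ids formed each charted point and its reference set.
    """

    chart_type: str
    spec: ChartSpec
    deviations: dict
    provenance: dict
    #: per plot, 1-based position of each charted point's time within the
    #: plot's time ordering (repeats under replicate-level charting)
    time_indices: dict = field(default_factory=dict)

    def pooled(self) -> np.ndarray:
        return np.concatenate([d for _, d in self.deviations.values()]) if self.deviations else np.array([])


@dataclass
class ControlLimits:
    """Bootstrapped percentile control limits.

    Baseline chart: one global limit per percentile.  Sequential chart: a
    limit per percentile per charted time index (dict time_index -> value;
    indices count charted points, starting at 2 = first charted time).
    """

    chart_type: str
    percentiles: tuple
    global_limits: dict | None        # percentile -> value  (baseline)
    per_time_limits: dict | None      # percentile -> {time_index: value}  (sequential)
    n_boot: int
    seed: int

    def limit(self, percentile: float, time_index: int | None = None) -> float:
        if self.chart_type == "baseline":
            return self.global_limits[percentile]
        if time_index is None:
            raise ValueError("sequential limits are time-point specific")
        return self.per_time_limits[percentile][time_index]


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def plot_time_points(metadata: pd.DataFrame, sample_ids=None) -> list:
    """Group samples into (plot, time) replicate sets, ordered in time.

    ``metadata`` is indexed by sample id with site/plot/time/replicate
    columns; plots are keyed by (site, plot).  Missing (plot, time) cells are
    simply absent (skipped with a warning when a plot lacks times another plot
    has).  Returns a list of :class:`PlotSeries`.
    """
    if sample_ids is None:
        sample_ids = list(metadata.index)
    pos = {s: i for i, s in enumerate(sample_ids)}
    md = metadata.loc[list(sample_ids)]
    all_times = sorted(set(md["time"].astype(str)), key=time_sort_key)
    series = []
    for (site, plot), sub in sorted(
        md.groupby([md["site"].astype(str), md["plot"].astype(str)], sort=True),
        key=lambda kv: kv[0],
    ):
        times_here = sorted(set(sub["time"].astype(str)), key=time_sort_key)
        missing = [t for t in all_times if t not in times_here]
        if missing:
            warnings.warn(
                f"plot {(site, plot)} missing time(s) {missing}; cells skipped",
                RuntimeWarning,
                stacklevel=2,
            )
        cells = []
        for t in times_here:
            ids = sub.index[sub["time"].astype(str) == t]
            cells.append(np.array([pos[s] for s in ids], dtype=int))
        series.append(PlotSeries(plot=(site, plot), times=times_here, cells=cells))
    return series


# ---------------------------------------------------------------------------
# Observed charts
# ---------------------------------------------------------------------------

def _sqrt_dev(val: float) -> float:
    return math.sqrt(max(0.0, val))


def _chart_points(ps: PlotSeries, spec: ChartSpec, first_index: int):
    """Charted points as (1-based time index, time label, index set).

    One point per (plot, time) centroid by default; under replicate-level
    charting every replicate becomes its own point (references and limits
    stay observation-level).
    """
    points = []
    for k in range(first_index - 1, len(ps.times)):
        if spec.replicate_level:
            for i in ps.cells[k]:
                points.append((k + 1, ps.times[k], np.array([i])))
        else:
            points.append((k + 1, ps.times[k], ps.cells[k]))
    return points


def chart_baseline(D: DissimilarityMatrix, metadata: pd.DataFrame, spec: ChartSpec) -> ControlChart:
    """Distance-to-baseline chart: d_t = distance of each (plot, time) centroid
    from the centroid of the plot's first ``m`` times (baseline times charted
    too; the baseline point of an m=1 chart is at zero by construction)."""
    layout = plot_time_points(metadata, D.sample_ids)
    m = spec.baseline_size
    deviations, provenance, time_indices = {}, {}, {}
    for ps in layout:
        if len(ps.times) < m:
            raise ValueError(
                f"plot {ps.plot} has {len(ps.times)} time point(s); baseline needs >= {m}"
            )
        base = np.concatenate(ps.cells[:m])
        points = _chart_points(ps, spec, first_index=1)
        d = np.array(
            [_sqrt_dev(centroid_sq_distance(D, cell, base)) for _, _, cell in points]
        )
        deviations[ps.plot] = ([t for _, t, _ in points], d)
        time_indices[ps.plot] = [idx for idx, _, _ in points]
        provenance[ps.plot] = {
            "baseline_samples": [D.sample_ids[i] for i in base],
            "points": [
                (t, [D.sample_ids[i] for i in cell]) for _, t, cell in points
            ],
        }
    return ControlChart(
        chart_type="baseline", spec=spec, deviations=deviations,
        provenance=provenance, time_indices=time_indices,
    )


def chart_sequential(D: DissimilarityMatrix, metadata: pd.DataFrame, spec: ChartSpec) -> ControlChart:
    """Distance-to-previous-centroid chart: d_t = distance of the (plot, time t)
    centroid from the centroid of all the plot's samples at times 1..t-1.
    No value exists at the first time."""
    layout = plot_time_points(metadata, D.sample_ids)
    deviations, provenance, time_indices = {}, {}, {}
    for ps in layout:
        if len(ps.times) < 2:
            raise ValueError(f"plot {ps.plot} needs >= 2 time points for a sequential chart")
        d, times = [], []
        prov_points = []
        for idx, t, cell in _chart_points(ps, spec, first_index=2):
            ref = np.concatenate(ps.cells[: idx - 1])
            d.append(_sqrt_dev(centroid_sq_distance(D, cell, ref)))
            times.append(t)
            prov_points.append((t, {
                "point": [D.sample_ids[i] for i in cell],
                "reference": [D.sample_ids[i] for i in ref],
            }))
        deviations[ps.plot] = (times, np.array(d))
        time_indices[ps.plot] = [idx for idx, _, _ in _chart_points(ps, spec, first_index=2)]
        provenance[ps.plot] = prov_points
    return ControlChart(
        chart_type="sequential", spec=spec, deviations=deviations,
        provenance=provenance, time_indices=time_indices,
    )


# ---------------------------------------------------------------------------
# Bootstrap control limits
# ---------------------------------------------------------------------------

def _cell_block_sums(D: DissimilarityMatrix, ps: PlotSeries) -> tuple[np.ndarray, np.ndarray]:
    """S[t1, t2] = full double sum of d^2 over cell t1 x cell t2, plus sizes."""
    d2 = D.values.astype(float) ** 2
    T = len(ps.cells)
    S = np.empty((T, T))
    for i in range(T):
        for j in range(T):
            S[i, j] = d2[np.ix_(ps.cells[i], ps.cells[j])].sum()
    sizes = np.array([c.size for c in ps.cells], dtype=float)
    return S, sizes


def _deviations_from_blocks(S: np.ndarray, sizes: np.ndarray, order: np.ndarray,
                            chart_type: str, m: int) -> np.ndarray:
    """Chart deviations for a (possibly resampled) cell sequence ``order``.

    Uses the centroid identity on block sums; repeated cells are handled as
    distinct copies (cross-sum between two copies of a cell is S[c, c]).
    Baseline chart returns one value per time position; sequential returns
    values for positions 2..T (length T-1).
    """
    T = order.size
    Ssub = S[np.ix_(order, order)]
    nsub = sizes[order]
    if chart_type == "baseline":
        out = np.empty(T)
        positions = range(T)
    else:
        out = np.empty(T - 1)
        positions = range(1, T)
    for k, t in enumerate(positions):
        ref = np.arange(min(m, T)) if chart_type == "baseline" else np.arange(t)
        nA = nsub[t]
        nB = nsub[ref].sum()
        sAB = Ssub[t, ref].sum()
        sAA = Ssub[t, t]
        sBB = Ssub[np.ix_(ref, ref)].sum()
        raw = sAB / (nA * nB) - sAA / (2.0 * nA**2) - sBB / (2.0 * nB**2)
        out[k] = math.sqrt(max(0.0, raw))
    return out


def bootstrap_limits(D: DissimilarityMatrix, metadata: pd.DataFrame, spec: ChartSpec) -> ControlLimits:
    """Bootstrap percentile control limits for the chart type in ``spec``.

    Each iteration resamples, within each plot independently, the plot's
    (plot, time) observations with replacement (a resampled observation keeps
    its full replicate set), assigns them to time positions 1..T in draw
    order, recomputes all chart deviations, pools them across plots
    (globally over time for the baseline chart, per charted time index for
    the sequential chart) and takes the requested percentiles
    (linear-interpolation empirical quantiles).  The limit is the mean of
    each percentile over the B iterations.
    """
    layout = plot_time_points(metadata, D.sample_ids)
    if not layout:
        raise ValueError("no plots found")
    for ps in layout:
        if len(ps.times) < 2:
            raise ValueError(f"plot {ps.plot} needs >= 2 time points")
    blocks = [_cell_block_sums(D, ps) for ps in layout]
    lengths = [len(ps.times) for ps in layout]
    rng = rng_for(spec.seed, "bootstrap", spec.chart_type)
    B = spec.n_boot

    if spec.chart_type == "baseline":
        percentile_draws = {p: np.empty(B) for p in spec.percentiles}
        for it in range(B):
            pooled = []
            for (S, sizes), T in zip(blocks, lengths):
                order = rng.integers(0, T, size=T)
                pooled.append(
                    _deviations_from_blocks(S, sizes, order, "baseline", spec.baseline_size)
                )
            pooled = np.concatenate(pooled)
            for p in spec.percentiles:
                percentile_draws[p][it] = np.percentile(pooled, p)
        return ControlLimits(
            chart_type="baseline",
            percentiles=spec.percentiles,
            global_limits={p: float(percentile_draws[p].mean()) for p in spec.percentiles},
            per_time_limits=None,
            n_boot=B,
            seed=spec.seed,
        )

    T_max = max(lengths)
    per_time_draws = {
        p: {t: np.empty(B) for t in range(2, T_max + 1)} for p in spec.percentiles
    }
    for it in range(B):
        devs_by_index: dict[int, list] = {t: [] for t in range(2, T_max + 1)}
        for (S, sizes), T in zip(blocks, lengths):
            order = rng.integers(0, T, size=T)
            d = _deviations_from_blocks(S, sizes, order, "sequential", spec.baseline_size)
            for k, val in enumerate(d):
                devs_by_index[k + 2].append(val)
        for t, vals in devs_by_index.items():
            if not vals:
                continue
            arr = np.asarray(vals)
            for p in spec.percentiles:
                per_time_draws[p][t][it] = np.percentile(arr, p)
    return ControlLimits(
        chart_type="sequential",
        percentiles=spec.percentiles,
        global_limits=None,
        per_time_limits={
            p: {t: float(v.mean()) for t, v in per_time_draws[p].items()}
            for p in spec.percentiles
        },
        n_boot=B,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# Flagging and tabulation
# ---------------------------------------------------------------------------

def flag_out_of_control(
    chart: ControlChart,
    limits: ControlLimits,
    flag_baseline_times: bool = False,
) -> pd.DataFrame:
    """Flag chart points above the 95th-percentile control limit.

    Returns a tidy frame (site, plot, time, deviation, cl50, cl95, flag,
    unstable).  Baseline-chart points at baseline times are charted but not
    flagged by default; the first charted sequential point (reference of a
    single time) carries an ``unstable`` annotation because the moving
    centroid needs time to stabilize.
    """
    if chart.chart_type != limits.chart_type:
        raise ValueError(
            f"chart type {chart.chart_type!r} does not match limits {limits.chart_type!r}"
        )
    lo_p = min(limits.percentiles)
    hi_p = max(limits.percentiles)
    rows = []
    for (site, plot), (times, devs) in chart.deviations.items():
        indices = chart.time_indices[(site, plot)]
        for t_index, t, d in zip(indices, times, devs):
            if chart.chart_type == "baseline":
                cl50 = limits.limit(lo_p)
                cl95 = limits.limit(hi_p)
                in_baseline = t_index <= chart.spec.baseline_size
                flag = bool(d > cl95) and (flag_baseline_times or not in_baseline)
                unstable = False
            else:
                cl50 = limits.limit(lo_p, t_index)
                cl95 = limits.limit(hi_p, t_index)
                flag = bool(d > cl95)
                unstable = t_index == 2
            rows.append(
                dict(site=site, plot=plot, time=t, chart_type=chart.chart_type,
                     deviation=d, cl50=cl50, cl95=cl95, flag=flag, unstable=unstable)
            )
    return pd.DataFrame(rows)


def chart_table(chart: ControlChart, limits: ControlLimits) -> pd.DataFrame:
    """Alias of :func:`flag_out_of_control`: the tidy chart export table."""
    return flag_out_of_control(chart, limits)


# ---------------------------------------------------------------------------
# Pseudo-plot assignment
# ---------------------------------------------------------------------------

def assign_pseudo_plots(metadata: pd.DataFrame, k: int, seed: int = 0) -> pd.Series:
    """Randomly partition each time's samples into k pseudo-plots.

    For sites sampled without distinct plots, replicates collected at the same
    time are assigned uniformly at random to k pseudo-sample plots
    ("pseudo-1".."pseudo-k"), with group sizes differing by at most one.
    Assignment is independent at each time and deterministic under the seed
    (label-keyed: the stream is consumed in sorted sample-id order).
    Returns a Series: sample id -> pseudo-plot label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = {}
    times = sorted(set(metadata["time"].astype(str)), key=time_sort_key)
    for t in times:
        ids = sorted(metadata.index[metadata["time"].astype(str) == t].astype(str))
        if len(ids) < k:
            raise ValueError(f"time {t!r} has {len(ids)} sample(s), fewer than k={k}")
        rng = rng_for(seed, "pseudo-plots", t)
        shuffled = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
        for pos, sid in enumerate(shuffled):
            out[sid] = f"pseudo-{pos % k + 1}"
    return pd.Series(out, name="plot").loc[[str(s) for s in metadata.index]]


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_control_charts(tables: list, path=None):
    """Render control charts (one panel per site x chart type) from tidy tables.

    ``tables`` is a list of frames from :func:`flag_out_of_control`.  Dashed
    lines mark the 50th and 95th percentile limits; flagged points are
    highlighted.  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.concat(tables, ignore_index=True)
    panels = sorted(df.groupby(["site", "chart_type"]).groups.keys())
    fig, axes = plt.subplots(
        len(panels), 1, figsize=(7, 2.8 * len(panels)), squeeze=False
    )
    markers = ["o", "s", "^", "D", "v", "P"]
    for ax, (site, ctype) in zip(axes[:, 0], panels):
        sub = df[(df["site"] == site) & (df["chart_type"] == ctype)]
        for mi, (plot, grp) in enumerate(sub.groupby("plot")):
            grp = grp.sort_values("time", key=lambda s: s.map(lambda x: time_sort_key(x)))
            ax.plot(grp["time"], grp["deviation"], marker=markers[mi % len(markers)],
                    label=f"plot {plot}")
            flagged = grp[grp["flag"]]
            if not flagged.empty:
                ax.scatter(flagged["time"], flagged["deviation"], s=120,
                           facecolors="none", edgecolors="red", zorder=5)
        grp = sub.sort_values("time", key=lambda s: s.map(lambda x: time_sort_key(x)))
        ax.plot(grp["time"], grp["cl50"], ls="--", c="grey", lw=1, label="50th limit")
        ax.plot(grp["time"], grp["cl95"], ls=(0, (5, 2)), c="black", lw=1, label="95th limit")
        ax.set_title(f"{site} — {ctype} chart")
        ax.set_ylabel("deviation (Bray–Curtis)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
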