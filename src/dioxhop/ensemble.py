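"""Ensemble statistics: chemiexcitation quantum yields, dissociation
half-times, population time series and RLSE feature classification.

The chemiexcitation quantum yield of a product electronic state is the
percentage of completed (dissociated) trajectories that end in that state;
the dissociation half-time is the sample median (midpoint convention for
even counts) of the per-state dissociation times.  RLSE - the relative
length of the subrange near an endpoint - quantifies how strongly extreme
initial velocities predispose trajectories to a product state: for a
scalar feature, a state's empty subrange at an endpoint is the distance
from the global range endpoint to that state's nearest value, expressed
as a percentage of the global range length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .analysis import PerTrajectorySummary, summarize_trajectory


@dataclass
class EnsembleResult:
    """Per-trajectory summaries for the completed part of an ensemble."""

    summaries: list[PerTrajectorySummary]
    n_launched: int
    n_completed: int
    n_failed: int
    dt: float = 0.5

    def __post_init__(self) -> None:
        if self.n_launched != self.n_completed + self.n_failed:
            raise ValueError("n_launched must equal n_completed + n_failed")


@dataclass(frozen=True)
class EndpointStat:
    lo: float
    hi: float
    empty_low: float
    empty_high: float
    rlse_low: float     # percent
    rlse_high: float    # percent


@dataclass(frozen=True)
class RLSEReport:
    feature: str
    lo: float
    hi: float
    per_state: dict[str, EndpointStat]


def collect_ensemble(records, r_dissoc: float = 2.4,
                     min_prominence: float = 0.05) -> EnsembleResult:
    """Summarize an ensemble of trajectory records.

    Completed trajectories are those that dissociated (reached the
    termination distance); energy failures and timeouts count as failed
    and contribute no summary.
    """
    summaries = []
    n_failed = 0
    for rec in records:
        if rec.status == "dissociated":
            summaries.append(summarize_trajectory(rec, r_dissoc, min_prominence))
        else:
            n_failed += 1
    return EnsembleResult(
        summaries=summaries, n_launched=len(records),
        n_completed=len(summaries), n_failed=n_failed,
        dt=records[0].dt if records else 0.5)


def quantum_yields(product_labels: Sequence[str], n_completed: int) -> dict[str, float]:
    """Percentage of completed trajectories ending in each product state."""
    if n_completed < 1:
        raise ValueError("quantum yields undefined for an empty ensemble")
    yields: dict[str, float] = {}
    for lab in product_labels:
        yields[lab] = yields.get(lab, 0.0) + 1.0
    return {lab: 100.0 * n / n_completed for lab, n in sorted(yields.items())}


def dissociation_half_time(times: Sequence[float]) -> float:
    """Time by which half of the trajectories have dissociated: the sample
    median, with the midpoint convention for even counts."""
    t = np.asarray([x for x in times if x is not None and np.isfinite(x)], dtype=float)
    if t.size == 0:
        raise ValueError("dissociation half-time undefined without any times")
    return float(np.median(t))


def dissociation_statistics(times: Sequence[float]) -> dict[str, float]:
    """min / max / half-time / mean / standard deviation of dissociation times."""
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("no dissociation times")
    return {
        "minimum": float(t.min()),
        "maximum": float(t.max()),
        "half_time": dissociation_half_time(t),
        "mean": float(t.mean()),
        "std": float(t.std(ddof=1)) if t.size > 1 else 0.0,
    }


def population_time_series(records, basis: str = "mch_collapsed",
                           t_grid: Sequence[float] | None = None):
    """Ensemble-averaged state populations on a common time grid.

    ``basis`` selects the state attribution per trajectory and time:

    * ``mch_collapsed`` - collapsed MCH label of the active state
      (triplet sublevels merged);
    * ``mch_full`` - full MCH label including the sz sublevel;
    * ``diagonal`` - index of the active diagonal state (``D1`` lowest).

    After a trajectory terminates its state is frozen at the last value
    (the product label), so late-time populations equal the quantum
    yields.  Returns ``(t_grid, {state: fractions})``; fractions sum to 1
    at every grid point.
    """
    records = [r for r in records if r.status == "dissociated"]
    if not records:
        raise ValueError("population series needs at least one completed record")
    if t_grid is None:
        t_end = max(float(r.t[-1]) for r in records)
        t_grid = np.arange(0.0, t_end + records[0].dt / 2, records[0].dt)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")

    def state_of(rec, j):
        if basis == "diagonal":
            return f"D{int(rec.active_diag[j]) + 1}"
        lab = rec.labels[rec.active_mch[j]]
        return lab.collapsed if basis == "mch_collapsed" else lab.name
    if basis not in ("mch_collapsed", "mch_full", "diagonal"):
        raise ValueError(f"unknown basis {basis!r}")

    pops: dict[str, np.ndarray] = {}
    for rec in records:
        idx = np.minimum(
            np.searchsorted(rec.t, t_grid, side="right") - 1, len(rec.t) - 1)
        idx = np.maximum(idx, 0)
        for k, j in enumerate(idx):
            s = state_of(rec, int(j))
            if s not in pops:
                pops[s] = np.zeros(t_grid.size)
            pops[s][k] += 1.0
    n = len(records)
    return t_grid, {s: arr / n for s, arr in sorted(pops.items())}


def detect_equilibrium(series: Mapping[str, np.ndarray], t_grid: Sequence[float],
                       window: float, tolerance: float = 0.01) -> float | None:
    """Earliest time from which every state's population stays within
    ``tolerance`` of its final value through the end of the series.

    Settling must hold for at least ``window`` fs before the series end
    (otherwise the last samples would qualify trivially); ``window`` must
    not exceed the series span.  Series that keep fluctuating beyond
    tolerance (e.g. triplet sz sublevels) return None.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2:
        raise ValueError("series too short")
    if window > t[-1] - t[0]:
        raise ValueError("window longer than the series span")
    ok = np.ones(t.size, dtype=bool)
    for arr in series.values():
        arr = np.asarray(arr, dtype=float)
        dev = np.abs(arr - arr[-1]) <= tolerance
        # suffix-AND: stable from i onward
        stable = np.logical_and.accumulate(dev[::-1])[::-1]
        ok &= stable
    idx = np.nonzero(ok)[0]
    if idx.size == 0 or t[idx[0]] > t[-1] - window:
        return None
    return float(t[idx[0]])


def histogram2d(x, y, x_edges, y_edges) -> np.ndarray:
    """2-D occupancy counts with right-open bins (last bin closed).

    Points on a shared interior edge land in the higher bin; the total
    equals the number of points inside the full range.
    """
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    for edges in (x_edges, y_edges):
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    return counts.astype(np.int64)


def rlse_report(feature_values: Mapping[str, Sequence[float]] | Sequence[float],
                product_labels: Sequence[str] | None = None,
                feature: str = "feature") -> RLSEReport:
    """Relative length of the subrange near each endpoint, per product state.

    Accepts either a mapping ``{state: values}`` or parallel value/label
    sequences.  The global range is [min, max] over all values; for each
    state the empty length at an endpoint is the distance from the global
    endpoint to the state's nearest value on that side, and RLSE is that
    length as a percentage of the global range length.
    """
    if product_labels is not None:
        grouped: dict[str, list[float]] = {}
        for val, lab in zip(feature_values, product_labels):  # type: ignore[arg-type]
            grouped.setdefault(lab, []).append(float(val))
    else:
        grouped = {k: [float(x) for x in v]
                   for k, v in feature_values.items()}  # type: ignore[union-attr]
    if not grouped or any(len(v) == 0 for v in grouped.values()):
        raise ValueError("every observed state needs at least one value")
    all_vals = np.concatenate([np.asarray(v, dtype=float) for v in grouped.values()])
    lo, hi = float(all_vals.min()), float(all_vals.max())
    length = hi - lo
    if length == 0.0:
        raise ValueError("zero global range length: RLSE undefined")
    per_state = {}
    for lab, vals in sorted(grouped.items()):
        v = np.asarray(vals, dtype=float)
        s_lo, s_hi = float(v.min()), float(v.max())
        empty_low = s_lo - lo
        empty_high = hi - s_hi
        per_state[lab] = EndpointStat(
            lo=s_lo, hi=s_hi, empty_low=empty_low, empty_high=empty_high,
            rlse_low=100.0 * empty_low / length,
            rlse_high=100.0 * empty_high / length)
    return RLSEReport(feature=feature, lo=lo, hi=hi, per_state=per_state)


def ensemble_report(result: EnsembleResult) -> dict:
    """Structured report: yields, per-product dissociation statistics and
    RLSE reports for every initial-velocity feature present."""
    products = [s.product for s in result.summaries]
    yields = quantum_yields(products, result.n_completed)
    by_product: dict[str, list[PerTrajectorySummary]] = {}
    for s in result.summaries:
        by_product.setdefault(s.product, []).append(s)
    stats = {lab: dissociation_statistics([s.dissociation_time for s in group])
             for lab, group in sorted(by_product.items())}
    all_stats = dissociation_statistics(
        [s.dissociation_time for s in result.summaries])
    feature_names = sorted({k for s in result.summaries for k in s.features})
    rlse = {}
    for name in feature_names:
        vals = [s.features[name] for s in result.summaries if name in s.features]
        labs = [s.product for s in result.summaries if name in s.features]
        try:
            rep = rlse_report(vals, labs, feature=name)
        except ValueError:
            continue
        rlse[name] = {
            "range": [rep.lo, rep.hi],
            "per_state": {
                lab: {"subrange": [st.lo, st.hi],
                      "rlse_low_pct": st.rlse_low, "rlse_high_pct": st.rlse_high}
                for lab, st in rep.per_state.items()},
        }
    return {
        "n_launched": result.n_launched,
        "n_completed": result.n_completed,
        "n_failed": result.n_failed,
        "quantum_yields_pct": yields,
        "dissociation_times": {"all": all_stats, **stats},
        "rlse": rlse,
    }
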