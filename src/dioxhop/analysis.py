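"""Per-trajectory statistics: dissociation detection, product labeling,
frustrated-dissociation counting, transition-count bookkeeping, residence
times and dihedral unwrapping.

Conventions (documented because they fix the printed half-fs arithmetic):

* the dissociation time is the time of the *first sample* whose C-C
  distance strictly exceeds the dissociation threshold — no interpolation
  between samples;
* a transition-count matrix over an N-sample state series holds N - 1
  transitions: the first sample is attributed to no state, and the
  per-state residence (destination convention) is the diagonal element
  plus the off-diagonal column sum, times the step size;
* dihedral angles live on (-180, 180] with -180 identified with +180;
  unwrapping lifts a wrapped series to a continuous path whose successive
  differences lie in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .model import wrap_degrees
from .states import SpinStateLabel


class UndefinedProductError(ValueError):
    """Product label requested for a trajectory that never dissociated."""


@dataclass(frozen=True)
class TransitionCountMatrix:
    """K x K integer matrix: diagonal = within-state steps, off-diagonal =
    hops, with ``counts[a, b]`` the number of a -> b transitions."""

    labels: tuple[SpinStateLabel, ...]
    counts: np.ndarray
    dt: float = 0.5

    @property
    def total_transitions(self) -> int:
        return int(self.counts.sum())


@dataclass
class PerTrajectorySummary:
    dissociation_time: float | None
    product: str | None              # collapsed label, e.g. 'T1'
    n_frustrated: int
    mean_period: float | None
    residence: dict[str, float]      # collapsed label -> fs
    angle_variation: float
    features: dict[str, float] = field(default_factory=dict)
    status: str = "dissociated"


def dissociation_time(record, r_dissoc: float = 2.4) -> float | None:
    """Time of the first sample with r_CC > ``r_dissoc``; None if never."""
    r = np.asarray(record.r_cc if hasattr(record, "r_cc") else record, dtype=float)
    t = np.asarray(record.t, dtype=float) if hasattr(record, "t") else None
    idx = np.nonzero(r > r_dissoc)[0]
    if idx.size == 0:
        return None
    if t is None:
        raise ValueError("record must carry a time axis")
    return float(t[idx[0]])


def _first_crossing_index(r: np.ndarray, r_dissoc: float) -> int | None:
    idx = np.nonzero(np.asarray(r) > r_dissoc)[0]
    return int(idx[0]) if idx.size else None


def product_state_label(record, r_dissoc: float = 2.4) -> str:
    """Collapsed MCH label at the first crossing of ``r_dissoc``.

    Triplet sz sublevels are collapsed to the parent triplet, so later
    sz-changing hops cannot alter the product assignment.
    """
    idx = _first_crossing_index(record.r_cc, r_dissoc)
    if idx is None:
        raise UndefinedProductError("trajectory never crossed the dissociation distance")
    label = record.labels[record.active_mch[idx]]
    return label.collapsed


def count_frustrated_dissociations(
        r_series: Sequence[float],
        min_prominence: float = 0.05,
        end_index: int | None = None) -> int:
    """Number of aborted bond-breaking attempts: interior strict local
    maxima of the C-C distance series with prominence >= ``min_prominence``
    (A), counted up to ``end_index`` (exclusive; pass the dissociation
    sample so post-dissociation structure is ignored)."""
    r = np.asarray(r_series, dtype=float)
    if end_index is not None:
        r = r[:end_index]
    if r.size < 3:
        return 0
    peaks, _ = find_peaks(r, prominence=min_prominence)
    return int(peaks.size)


def mean_oscillation_period(n_peaks: int, window: float) -> float | None:
    """Average C-C oscillation period: counting window divided by the
    number of frustrated dissociations; None when there were no peaks."""
    if n_peaks == 0:
        return None
    return window / n_peaks


def transition_count_matrix(
        mch_series: Sequence[SpinStateLabel],
        dt: float = 0.5,
        labels: Sequence[SpinStateLabel] | None = None) -> TransitionCountMatrix:
    """Count step-to-step transitions of an MCH label series.

    ``counts[a, a]`` increments for every consecutive pair within state a,
    ``counts[a, b]`` for every a -> b hop; the grand total is
    ``len(series) - 1``.
    """
    series = list(mch_series)
    if len(series) < 2:
        raise ValueError("state series needs at least two samples")
    if labels is None:
        labels = sorted(set(series))
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for prev, curr in zip(series[:-1], series[1:]):
        try:
            counts[index[prev], index[curr]] += 1
        except KeyError as exc:
            raise ValueError(f"state {exc.args[0]} not in the label set") from exc
    return TransitionCountMatrix(labels=labels, counts=counts, dt=dt)


def residence_times(matrix: TransitionCountMatrix) -> tuple[dict[str, float], dict[str, float]]:
    """Per-state and collapsed residence times from a transition-count matrix.

    The steps attributed to a state are its diagonal element plus the sum
    of the off-diagonal elements in its *column* (hops arriving there);
    residence time is steps times the step size.  Collapsed totals sum the
    sz sublevels of each triplet.  Returns ``(per_label, collapsed)`` maps
    keyed by label names.
    """
    counts = matrix.counts
    col_sums = counts.sum(axis=0)
    steps = np.diag(counts) + (col_sums - np.diag(counts))
    per_label = {lab.name: float(s * matrix.dt) for lab, s in zip(matrix.labels, steps)}
    collapsed: dict[str, float] = {}
    for lab, s in zip(matrix.labels, steps):
        collapsed[lab.collapsed] = collapsed.get(lab.collapsed, 0.0) + float(s * matrix.dt)
    return per_label, collapsed


def unwrap_dihedral(wrapped_series: Sequence[float]) -> np.ndarray:
    """Lift a wrapped dihedral series (degrees) to a continuous path.

    Successive differences of the output lie in (-180, 180] and the output
    is congruent to the input modulo 360.
    """
    x = np.asarray(wrapped_series, dtype=float)
    if x.size == 0:
        return x.copy()
    diffs = wrap_degrees(np.diff(x))
    return np.concatenate(([x[0]], x[0] + np.cumsum(diffs)))


def angle_variation(series: Sequence[float]) -> float:
    """Total dihedral-angle change |unwrapped final - initial| in degrees."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two angle values")
    unwrapped = unwrap_dihedral(x)
    return float(abs(unwrapped[-1] - unwrapped[0]))


def summarize_trajectory(
        record,
        r_dissoc: float = 2.4,
        min_prominence: float = 0.05) -> PerTrajectorySummary:
    """All per-trajectory statistics in one pass."""
    idx = _first_crossing_index(record.r_cc, r_dissoc)
    t_diss = float(record.t[idx]) if idx is not None else None
    product = record.labels[record.active_mch[idx]].collapsed if idx is not None else None
    n_frustrated = count_frustrated_dissociations(
        record.r_cc, min_prominence=min_prominence, end_index=idx)
    period = mean_oscillation_period(n_frustrated, t_diss) if t_diss else None
    matrix = transition_count_matrix(record.mch_series, dt=record.dt, labels=record.labels)
    _, collapsed = residence_times(matrix)
    end = idx + 1 if idx is not None else len(record.phi_oocc)
    variation = angle_variation(record.phi_oocc[:end]) if end >= 2 else 0.0
    feats = dict(record.initial.features) if record.initial is not None else {}
    return PerTrajectorySummary(
        dissociation_time=t_diss, product=product, n_frustrated=n_frustrated,
        mean_period=period, residence=collapsed, angle_variation=variation,
        features=feats, status=record.status)
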