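"""Reference data for the dimethyl-dioxetane thermolysis study, as printed.

Small literature-derived tables used for worked examples and validation:
transition-count matrices for a representative short and long triplet-
product trajectory, the product-state trajectory counts of the full
310-trajectory ensemble, the dihedral waypoint sequence of the long
trajectory, and the initial-angular-velocity ranges behind the published
RLSE (relative length of the subrange near an endpoint) percentages.

State columns follow the canonical MCH order
S0, S1, S2, S3, T1,-1, T2,-1, T1,0, T2,0, T1,1, T2,1.
"""

from __future__ import annotations

import numpy as np

from .analysis import TransitionCountMatrix
from .states import parse_label

_TABLE_LABELS = tuple(parse_label(s) for s in (
    "S0", "S1", "S2", "S3", "T1,-1", "T2,-1", "T1,0", "T2,0", "T1,1", "T2,1"))

# Nonadiabatic transition counts, short trajectory with a T1 product
# (159 transitions = 160 samples over 79.5 fs at 0.5 fs).
_TABLE2 = np.array([
    [59, 0, 0, 0, 1, 0, 0, 0, 0, 0],
    [1, 10, 0, 0, 0, 0, 0, 0, 0, 0],
    [0,  0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0,  0, 0, 0, 0, 0, 0, 0, 0, 0],
    [1,  0, 0, 0, 5, 0, 0, 1, 0, 0],
    [0,  1, 0, 0, 0, 0, 0, 0, 0, 0],
    [0,  0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0,  0, 0, 0, 0, 1, 0, 1, 0, 0],
    [0,  0, 0, 0, 1, 0, 0, 0, 60, 1],
    [0,  0, 0, 0, 0, 0, 0, 0, 1, 15],
], dtype=np.int64)

# Nonadiabatic transition counts, long trajectory with a T1 product.
_TABLE3 = np.array([
    [51,  0, 1, 0,   2,   0,   5,   1,   0,   0],
    [4, 203, 4, 1,   2,   1,   0,   8,   1,   3],
    [0,   4, 42, 0,  1,   0,   0,   1,   0,   1],
    [0,   0, 1, 24,  0,   0,   0,   0,   0,   0],
    [3,   1, 0, 0, 474,   3,  14,   1,  16,   2],
    [0,   4, 0, 0,   3, 176,   0,   8,   1,  10],
    [2,   3, 0, 0,  14,   0, 266,   4,  16,   0],
    [0,   8, 0, 0,   1,   7,   4, 219,   0,   9],
    [1,   0, 0, 0,  16,   1,  15,   1, 239,   1],
    [0,   4, 1, 0,   1,  14,   0,   5,   1, 158],
], dtype=np.int64)

# Product-state trajectory counts over the 302 completed trajectories.
_TABLE4_COUNTS = {"S0": 180, "S1": 52, "S2": 0, "S3": 0, "T1": 70, "T2": 0}

# Dihedral waypoints (degrees) of the long trajectory: 135.8 -> 180(-180)
# -> -90 -> 0 -> 32.9, a total variation of 257.1 degrees once unwrapped.
_WAYPOINTS_TRAJ23 = [135.8, 180.0, -90.0, 0.0, 32.9]

# Initial-velocity feature ranges behind the published RLSE percentages.
# omega0_1234 subranges are printed directly; the remaining features'
# numeric ranges are synthetic reconstructions chosen to reproduce the
# published percentages exactly (20.0, 25.0, 12.5, 23.1, 33.3).
_RLSE_RANGES = {
    "omega0_1234": {            # deg/fs, global range [-3.0, 2.0], length 5.0
        "T1": (-3.0, 1.5),
        "S0": (-2.0, 2.0),      # empty low 1.0 -> 20.0% RLSE
        "S1": (-2.5, 1.0),      # empty high 1.0 -> 20.0% RLSE
    },
    "omega0_3456": {            # deg/fs, global [-2.0, 3.0]; T1 misses the
        "T1": (-1.0, 3.0),      # low decile: empty low 1.0 -> 20.0% RLSE
        "S0": (-2.0, 3.0),
        "S1": (-2.0, 2.5),
    },
    "v0_12": {                  # synthetic: global [0.0, 8.0]
        "S0": (0.0, 7.0),       # empty high 1.0 -> 12.5% RLSE
        "S1": (2.0, 8.0),       # empty low 2.0 -> 25.0% RLSE
        "T1": (2.0, 7.0),
    },
    "v0_34": {                  # synthetic: global [-6.5, 6.5], length 13.0
        "S0": (-6.5, 6.5),
        "S1": (-6.5, 3.5),      # empty high 3.0 -> 23.1% RLSE
        "T1": (-3.5, 6.5),      # empty low 3.0 -> 23.1% RLSE
    },
    "v0_56": {                  # synthetic: global [-3.0, 3.0], length 6.0
        "S0": (-3.0, 3.0),
        "S1": (-3.0, 3.0),
        "T1": (-3.0, 1.0),      # empty high 2.0 -> 33.3% RLSE
    },
}

_FIXTURES = {
    "table2_matrix": lambda: TransitionCountMatrix(
        labels=_TABLE_LABELS, counts=_TABLE2.copy(), dt=0.5),
    "table3_matrix": lambda: TransitionCountMatrix(
        labels=_TABLE_LABELS, counts=_TABLE3.copy(), dt=0.5),
    "table4_counts": lambda: dict(_TABLE4_COUNTS),
    "dihedral_waypoints_traj23": lambda: list(_WAYPOINTS_TRAJ23),
    "rlse_ranges_fig5": lambda: {k: dict(v) for k, v in _RLSE_RANGES.items()},
}


def load_fixture(name: str):
    """Return one of the shipped reference objects by name.

    Known names: ``table2_matrix``, ``table3_matrix``, ``table4_counts``,
    ``dihedral_waypoints_traj23``, ``rlse_ranges_fig5``.
    """
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}") from None
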