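"""Trajectory table dialect: one tab-delimited text file per trajectory
plus a JSON sidecar with the scalar summary.

The table starts with a header line naming the columns; column order is
free on read (columns are matched by name).  Canonical column order on
write: ``t``, the coordinates ``q_<name>``, the velocities ``v_<name>``,
``active_diag``, ``active_mch`` (state-label text), ``e_active``,
``e_total``, ``r_cc``, ``phi_oocc``, ``phi_cccc``.  Angles are degrees,
energies eV, times fs.  Floats are written with ``repr`` precision so a
read-back record is bitwise-equal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .engine import HopEvent, TrajectoryRecord
from .states import parse_label


class TrajectoryParseError(ValueError):
    """Malformed trajectory table; the message carries the line number."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trajectory(record: TrajectoryRecord, path) -> Path:
    """Write the step table to ``path`` and the summary sidecar next to it."""
    path = Path(path)
    if record.n_steps < 1:
        raise ValueError("cannot write a trajectory with no steps")
    d = record.q.shape[1]
    coord_names = [f"c{i}" for i in range(d)]
    header = (["t"] + [f"q_{n}" for n in coord_names] + [f"v_{n}" for n in coord_names]
              + ["active_diag", "active_mch", "e_active", "e_total",
                 "r_cc", "phi_oocc", "phi_cccc"])
    lines = ["\t".join(header)]
    for i in range(record.n_steps):
        row = [repr(float(record.t[i]))]
        row += [repr(float(x)) for x in record.q[i]]
        row += [repr(float(x)) for x in record.v[i]]
        row.append(str(int(record.active_diag[i])))
        row.append(record.labels[record.active_mch[i]].name)
        row += [repr(float(record.e_active[i])), repr(float(record.e_total[i]))]
        row += [repr(float(record.r_cc[i])), repr(float(record.phi_oocc[i])),
                repr(float(record.phi_cccc[i]))]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    summary = {
        "dt": record.dt,
        "status": record.status,
        "labels": [l.name for l in record.labels],
        "product_mch": record.product_mch.name if record.product_mch else None,
        "dissociation_time": record.dissociation_time,
        "label_consistent": record.label_consistent,
        "hops": [
            {"t": h.t, "from_diag": h.from_diag, "to_diag": h.to_diag,
             "from_mch": h.from_mch.name, "to_mch": h.to_mch.name,
             "frustrated": h.frustrated,
             "used_fallback_direction": h.used_fallback_direction}
            for h in record.hops],
        "initial": None if record.initial is None else {
            "seed": record.initial.seed,
            "kinetic_energy": record.initial.kinetic_energy,
            "features": record.initial.features,
        },
    }
    _sidecar_path(path).write_text(json.dumps(summary, indent=1), encoding="utf-8")
    return path


def read_trajectory(path) -> TrajectoryRecord:
    """Parse a trajectory table (+ sidecar) back into a record."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    if not text:
        raise TrajectoryParseError(f"{path}: empty file")
    header = text[0].split("\t")
    col = {name: i for i, name in enumerate(header)}
    q_cols = sorted((n for n in col if n.startswith("q_")),
                    key=lambda n: int(n[3:]))
    v_cols = sorted((n for n in col if n.startswith("v_")),
                    key=lambda n: int(n[3:]))
    required = ["t", "active_diag", "active_mch", "e_active", "e_total",
                "r_cc", "phi_oocc", "phi_cccc"]
    for name in required:
        if name not in col:
            raise TrajectoryParseError(f"{path}: missing column {name!r}")
    if not q_cols or len(q_cols) != len(v_cols):
        raise TrajectoryParseError(f"{path}: inconsistent coordinate columns")

    rows = text[1:]
    if not rows:
        raise TrajectoryParseError(f"{path}: trajectory needs at least one step (line 2)")
    n, d = len(rows), len(q_cols)
    t = np.empty(n); q = np.empty((n, d)); v = np.empty((n, d))
    diag = np.empty(n, dtype=np.int64)
    mch_names = []
    e_act = np.empty(n); e_tot = np.empty(n)
    r_cc = np.empty(n); p1 = np.empty(n); p2 = np.empty(n)
    for i, line in enumerate(rows):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise TrajectoryParseError(
                f"{path}: line {i + 2}: expected {len(header)} fields, got {len(parts)}")
        try:
            t[i] = float(parts[col["t"]])
            for j, name in enumerate(q_cols):
                q[i, j] = float(parts[col[name]])
            for j, name in enumerate(v_cols):
                v[i, j] = float(parts[col[name]])
            diag[i] = int(parts[col["active_diag"]])
            mch_names.append(parts[col["active_mch"]])
            e_act[i] = float(parts[col["e_active"]])
            e_tot[i] = float(parts[col["e_total"]])
            r_cc[i] = float(parts[col["r_cc"]])
            p1[i] = float(parts[col["phi_oocc"]])
            p2[i] = float(parts[col["phi_cccc"]])
        except ValueError as exc:
            raise TrajectoryParseError(f"{path}: line {i + 2}: {exc}") from None

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise TrajectoryParseError(f"{path}: missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    labels = [parse_label(s) for s in meta["labels"]]
    label_index = {l.name: i for i, l in enumerate(labels)}
    try:
        mch = np.array([label_index[name] for name in mch_names], dtype=np.int64)
    except KeyError as exc:
        raise TrajectoryParseError(f"{path}: unknown state label {exc.args[0]!r}") from None
    hops = [HopEvent(
        t=h["t"], from_diag=h["from_diag"], to_diag=h["to_diag"],
        from_mch=parse_label(h["from_mch"]), to_mch=parse_label(h["to_mch"]),
        frustrated=h["frustrated"],
        used_fallback_direction=h.get("used_fallback_direction", False))
        for h in meta.get("hops", [])]
    product = parse_label(meta["product_mch"]) if meta.get("product_mch") else None
    return TrajectoryRecord(
        labels=labels, t=t, q=q, v=v, active_diag=diag, active_mch=mch,
        e_active=e_act, e_total=e_tot, r_cc=r_cc, phi_oocc=p1, phi_cccc=p2,
        hops=hops, status=meta["status"], product_mch=product,
        dissociation_time=meta.get("dissociation_time"),
        initial=None, label_consistent=meta.get("label_consistent", True),
        dt=meta.get("dt", 0.5))


def read_mch_series(path) -> list:
    """Read a standalone MCH-state series: one label per line (``S0``,
    ``T1,-1`` ... ), blank lines and ``#`` comments ignored."""
    out = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            out.append(parse_label(line))
        except ValueError as exc:
            raise TrajectoryParseError(f"{path}: line {i + 1}: {exc}") from None
    return out
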