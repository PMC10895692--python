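"""Electronic-state labels for the spin-free (MCH) basis.

States of the molecular Coulomb Hamiltonian carry good quantum numbers
``S`` (total spin, here via the multiplicity 2S+1) and ``S_z``.  A singlet
contributes one basis state, a triplet three (one per ``S_z`` sublevel).
The canonical ordering is the one used by transition-count tables for this
system: singlets by index first, then triplet sublevels grouped by ``S_z``
(-1, 0, +1) and, within an ``S_z`` block, by triplet index; restricted to
S0..S3, T1, T2 this reads

    S0, S1, S2, S3, T1,-1, T2,-1, T1,0, T2,0, T1,1, T2,1
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering
from typing import Iterator


@total_ordering
@dataclass(frozen=True)
class SpinStateLabel:
    """Identity of one MCH basis state.

    Parameters
    ----------
    multiplicity : int
        1 for singlets, 3 for triplets.
    index : int
        Zero-based index within the multiplicity, so ``index=0`` is S0 for
        singlets but T1 for triplets (chemical numbering starts triplets
        at 1).
    sz : int
        ``S_z`` sublevel: 0 for singlets, one of {-1, 0, +1} for triplets.
    """

    multiplicity: int
    index: int
    sz: int = 0

    def __post_init__(self) -> None:
        if self.multiplicity not in (1, 3):
            raise ValueError(f"multiplicity must be 1 or 3, got {self.multiplicity}")
        if self.index < 0:
            raise ValueError(f"index must be >= 0, got {self.index}")
        if self.multiplicity == 1 and self.sz != 0:
            raise ValueError("singlets have sz = 0")
        if self.multiplicity == 3 and self.sz not in (-1, 0, 1):
            raise ValueError(f"triplet sz must be in {{-1, 0, 1}}, got {self.sz}")

    @property
    def sort_key(self) -> tuple[int, int, int]:
        # sz-major ordering within a multiplicity (SHARC/MCH table order)
        return (self.multiplicity, self.sz, self.index)

    def __lt__(self, other: "SpinStateLabel") -> bool:
        return self.sort_key < other.sort_key

    @property
    def collapsed(self) -> str:
        """State name with the triplet sz sublevel dropped (T1,0 -> 'T1')."""
        letter = "S" if self.multiplicity == 1 else "T"
        chem_index = self.index if self.multiplicity == 1 else self.index + 1
        return f"{letter}{chem_index}"

    @property
    def name(self) -> str:
        if self.multiplicity == 1:
            return self.collapsed
        return f"{self.collapsed},{self.sz:+d}".replace("+", "")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def parse_label(text: str) -> SpinStateLabel:
    """Parse a label like ``'S0'``, ``'T1,-1'`` or ``'T2,0'``."""
    text = text.strip()
    letter = text[0].upper()
    if letter not in ("S", "T"):
        raise ValueError(f"unknown state label {text!r}")
    if letter == "S":
        return SpinStateLabel(1, int(text[1:]), 0)
    body = text[1:]
    if "," in body:
        idx, sz = body.split(",")
        return SpinStateLabel(3, int(idx) - 1, int(sz))
    raise ValueError(f"triplet label needs an sz component: {text!r}")


def state_labels(n_singlets: int, n_triplets: int) -> list[SpinStateLabel]:
    """Full ordered MCH basis for ``n_singlets`` singlets and ``n_triplets`` triplets."""
    labels = [SpinStateLabel(1, i, 0) for i in range(n_singlets)]
    for sz in (-1, 0, 1):
        labels.extend(SpinStateLabel(3, i, sz) for i in range(n_triplets))
    return labels


def iter_triplet_sublevels(label: SpinStateLabel) -> Iterator[SpinStateLabel]:
    """The three sz sublevels of the triplet ``label`` belongs to."""
    if label.multiplicity != 3:
        raise ValueError("not a triplet label")
    for sz in (-1, 0, 1):
        yield SpinStateLabel(3, label.index, sz)
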