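"""Hydrogen-bond-based helix assignment and helix-regularity measures.

A compact Kabsch–Sander-style assignment: backbone amide hydrogens (absent
from crystal structures) are reconstructed geometrically, hydrogen-bond
energies are evaluated with the classic electrostatic model

    E = 0.084 * 332 * (1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)   [kcal/mol],

a bond being counted below −0.5 kcal/mol, and α-helices are called from runs
of i→i+4 bonds (two consecutive bonds start a helix).  Only the helix-type
patterns are assigned (H, and the analogous G/I patterns from i→i+3 / i→i+5
bonds); sheet bookkeeping is out of scope.  A windowed kink angle quantifies
whether a helix is straight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BackboneResidue",
    "SSAssignment",
    "reconstruct_amide_h",
    "hbond_energy",
    "assign_helix",
    "kink_angle",
    "backbone_from_chain",
]

HBOND_CUTOFF = -0.5   # kcal/mol
_KS_FACTOR = 0.084 * 332.0
_CLASH_ENERGY = -9.9


@dataclass
class BackboneResidue:
    """Backbone heavy atoms of one residue plus the reconstructed amide H."""

    resname: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray | None = None  # None for chain start and proline

    def __post_init__(self) -> None:
        for name in ("n", "ca", "c", "o"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if self.h is not None:
            self.h = np.asarray(self.h, dtype=float).reshape(3)
        for d, pair in ((np.linalg.norm(self.n - self.ca), "N–CA"),
                        (np.linalg.norm(self.ca - self.c), "CA–C")):
            if not 1.2 <= d <= 1.8:
                raise ValueError(f"{self.resname}: {pair} distance {d:.2f} Å outside 1.2–1.8")


def reconstruct_amide_h(prev_c: np.ndarray, prev_o: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Place the amide H 1.0 Å from N, opposing the preceding carbonyl.

    H = N + normalize( normalize(N − C_prev) + normalize(C_prev − O_prev) ).
    """
    prev_c = np.asarray(prev_c, dtype=float)
    prev_o = np.asarray(prev_o, dtype=float)
    n = np.asarray(n, dtype=float)
    v1 = n - prev_c
    v2 = prev_c - prev_o
    v = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
    return n + v / np.linalg.norm(v)


def _with_hydrogens(residues: list[BackboneResidue]) -> list[BackboneResidue]:
    for i, res in enumerate(residues):
        if res.h is not None or i == 0 or res.resname.upper() in ("PRO", "P"):
            continue
        prev = residues[i - 1]
        res.h = reconstruct_amide_h(prev.c, prev.o, res.n)
    return residues


def hbond_energy(donor: BackboneResidue, acceptor: BackboneResidue) -> float:
    """Kabsch–Sander electrostatic energy of the N–H(donor)···O=C(acceptor) pair."""
    if donor.h is None:
        raise ValueError("donor has no amide hydrogen (chain start or proline)")
    if donor is acceptor:
        raise ValueError("donor and acceptor must differ")
    d_on = np.linalg.norm(acceptor.o - donor.n)
    d_ch = np.linalg.norm(acceptor.c - donor.h)
    d_oh = np.linalg.norm(acceptor.o - donor.h)
    d_cn = np.linalg.norm(acceptor.c - donor.n)
    if min(d_on, d_ch, d_oh, d_cn) < 0.5:
        return _CLASH_ENERGY
    return float(_KS_FACTOR * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn))


@dataclass
class SSAssignment:
    """Per-residue secondary-structure labels and i→i+4 bond energies."""

    labels: str                 # alphabet: H G I T -
    energies_i4: np.ndarray     # energies_i4[i] = E(donor i+4 -> acceptor i), NaN if undefined

    def helix_fraction(self) -> float:
        return self.labels.count("H") / max(len(self.labels), 1)


def _turn_bonds(residues: list[BackboneResidue], span: int) -> np.ndarray:
    """bond[i] True when CO(i) accepts from NH(i+span)."""
    n = len(residues)
    bonds = np.zeros(n, dtype=bool)
    energies = np.full(n, np.nan)
    for i in range(n - span):
        donor = residues[i + span]
        if donor.h is None:
            continue
        e = hbond_energy(donor, residues[i])
        energies[i] = e
        bonds[i] = e < HBOND_CUTOFF
    return bonds, energies


def assign_helix(residues: list[BackboneResidue]) -> SSAssignment:
    """Assign helix labels from backbone hydrogen bonding.

    Two consecutive i→i+4 turns (bonds CO(i−1)←NH(i+3) and CO(i)←NH(i+4))
    make residues i..i+3 α-helical (H).  The same pattern on i→i+3 / i→i+5
    turns yields G (3₁₀) and I (π) where not already H; single turns leave a
    T.  Requires at least 5 residues.
    """
    if len(residues) < 5:
        raise ValueError(f"need at least 5 residues, got {len(residues)}")
    residues = _with_hydrogens(list(residues))
    n = len(residues)
    labels = np.array(["-"] * n, dtype=object)

    bonds5, _ = _turn_bonds(residues, 5)
    bonds3, _ = _turn_bonds(residues, 3)
    bonds4, energies4 = _turn_bonds(residues, 4)

    for span, bonds, code in ((5, bonds5, "I"), (3, bonds3, "G"), (4, bonds4, "H")):
        for i in range(1, n - span):
            if bonds[i - 1] and bonds[i]:
                for j in range(i, i + span):
                    if code == "H" or labels[j] == "-":
                        labels[j] = code
    # leftover single turns
    for span, bonds in ((3, bonds3), (4, bonds4), (5, bonds5)):
        for i in np.flatnonzero(bonds):
            for j in range(i + 1, min(i + span, n)):
                if labels[j] == "-":
                    labels[j] = "T"
    return SSAssignment("".join(labels), energies4)


def kink_angle(ca_coords: np.ndarray, window: int = 7) -> np.ndarray:
    """Windowed bend angle (degrees) along a helix Cα trace.

    At every interior position i (window ≤ i ≤ n−1−window) the angle between
    the principal axes of the preceding and following ``window``+1 Cαs is
    reported; a straight helix stays below a few degrees, a kink shows up as
    a localized maximum near the bend.
    """
    ca = np.asarray(ca_coords, dtype=float)
    n = ca.shape[0]
    if n < 2 * window + 1:
        raise ValueError(f"helix of {n} residues too short for window {window}")

    def axis(seg: np.ndarray) -> np.ndarray:
        c = seg.mean(axis=0)
        _, _, vt = np.linalg.svd(seg - c)
        u = vt[0]
        return u if u @ (seg[-1] - seg[0]) >= 0 else -u

    out = np.full(n, np.nan)
    for i in range(window, n - window):
        u1 = axis(ca[i - window:i + 1])
        u2 = axis(ca[i:i + window + 1])
        out[i] = np.degrees(np.arccos(np.clip(u1 @ u2, -1.0, 1.0)))
    return out


def backbone_from_chain(chain) -> list[BackboneResidue]:
    """Build BackboneResidues (with reconstructed hydrogens) from a ChainModel."""
    from .structure_io import resolved_atoms

    out: list[BackboneResidue] = []
    for key, atoms in chain.residues:
        coords = resolved_atoms(atoms)
        if not {"N", "CA", "C", "O"} <= set(coords):
            continue
        out.append(BackboneResidue(key.residue_name, coords["N"], coords["CA"],
                                   coords["C"], coords["O"]))
    return _with_hydrogens(out)
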