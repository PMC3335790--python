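"""Synthetic 7-helix bundles with known ground-truth geometry.

Every pipeline stage in this package is testable offline against structures
generated here: ideal α-helices (canonical 1.5 Å rise, 100°/residue twist,
2.3 Å Cα radius) arranged as an antiparallel seven-helix bundle, with
controllable rigid-body displacement of individual helices and seeded
Gaussian coordinate noise.  Backbone N/C/O atoms are placed on co-axial
helical curves whose cylindrical offsets were frozen from ideal φ=−57°,
ψ=−47° internal geometry, so the hydrogen-bond-based assignment in
:mod:`tmbundle.secstruct` recognises the helices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .numbering import (DEFAULT_DEFINITION, BundleDefinition, BWNumber,
                        ReceptorMap, bw_to_author)
from .secstruct import BackboneResidue, reconstruct_amide_h
from .structure_io import AtomRecord, ChainModel, ResidueKey, one_to_three, write_chain_pdb

__all__ = [
    "HelixSpec",
    "PerturbationSpec",
    "ideal_helix",
    "default_layout",
    "build_bundle",
    "add_ionic_lock_sidechains",
    "perturb",
    "make_ensemble",
]

# cylindrical offsets (radius Å, phase deg, z Å) of backbone atoms relative
# to the Cα helix, frozen from ideal alpha-helix internal coordinates
_BACKBONE_OFFSETS = {
    "N": (1.559, -26.80, -0.919),
    "C": (1.665, 26.67, 1.069),
    "O": (1.924, 20.13, 2.255),
}


@dataclass(frozen=True)
class HelixSpec:
    """Parametric ideal α-helix: geometry of the Cα curve plus placement."""

    length: int
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    phase: float = 0.0          # degrees
    rise: float = 1.5           # Å / residue
    twist: float = 100.0        # degrees / residue
    radius: float = 2.3         # Å, Cα

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError(f"helix length must be ≥ 4, got {self.length}")
        axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


@dataclass(frozen=True)
class PerturbationSpec:
    """Rigid-body displacement of one helix plus isotropic coordinate noise."""

    helix: int = 3
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    rotation_angle: float = 0.0  # degrees, about the axis through the helix centroid
    sigma: float = 0.0           # Å, Gaussian noise on every atom
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 7:
            raise ValueError(f"helix must be 1..7, got {self.helix}")
        if self.sigma < 0:
            raise ValueError("sigma must be ≥ 0")
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        object.__setattr__(self, "rotation_axis", np.asarray(self.rotation_axis, dtype=float))


def _frame_for_axis(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is ``axis`` (columns = local x,y,z)."""
    z = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - (ref @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def ideal_helix(spec: HelixSpec, with_backbone: bool = True,
                resnames: list[str] | None = None) -> list[BackboneResidue]:
    """Generate one ideal α-helix as a list of BackboneResidues.

    Cαs lie exactly on the parametric curve defined by ``spec``; with
    ``with_backbone`` the N/C/O atoms are placed on co-axial offset curves
    reproducing ideal α-helical internal geometry (amide hydrogens are
    reconstructed, so Kabsch–Sander assignment labels the helix H).
    """
    n = spec.length
    if resnames is None:
        resnames = ["ALA"] * n
    frame = _frame_for_axis(spec.axis)
    i = np.arange(n)

    def curve(radius: float, dphase: float, dz: float) -> np.ndarray:
        th = np.deg2rad(spec.twist * i + spec.phase + dphase)
        local = np.stack([radius * np.cos(th), radius * np.sin(th),
                          spec.rise * i + dz], axis=1)
        return local @ frame.T + spec.origin

    ca = curve(spec.radius, 0.0, 0.0)
    if not with_backbone:
        # minimal stand-in backbone so the container's invariants hold
        nxt = np.vstack([ca[1:], 2 * ca[-1] - ca[-2]])
        d = nxt - ca
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return [BackboneResidue(resnames[k], ca[k] - 1.46 * d[k], ca[k],
                                ca[k] + 1.52 * d[k], ca[k] + 1.52 * d[k] + [0, 0, 1.23])
                for k in range(n)]
    atoms = {name: curve(*off) for name, off in _BACKBONE_OFFSETS.items()}
    out = []
    for k in range(n):
        res = BackboneResidue(resnames[k], atoms["N"][k], ca[k], atoms["C"][k], atoms["O"][k])
        if k > 0 and res.resname != "PRO":
            res.h = reconstruct_amide_h(atoms["C"][k - 1], atoms["O"][k - 1], res.n)
        out.append(res)
    return out


def default_layout(definition: BundleDefinition = DEFAULT_DEFINITION,
                   circle_radius: float = 12.0) -> list[HelixSpec]:
    """Seven helix specs on a circle, antiparallel alternation.

    Helix centroids sit on a circle (default radius 12 Å) in the order
    I→VII; odd helices run N→C toward the cytoplasmic side (−z) and even
    helices toward the extracellular side (+z), matching GPCR topology so
    that e.g. 4.39 lies at the cytoplasmic end.  Purely a qualitative mimic
    of the fold — no receptor-specific packing.
    """
    specs = []
    for h in range(1, 8):
        length = definition.helix_length(h)
        angle = 2 * np.pi * (h - 1) / 7
        center = circle_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        down = h % 2 == 1
        axis = np.array([0.0, 0.0, -1.0 if down else 1.0])
        origin = center - axis * (length - 1) * 1.5 / 2.0
        specs.append(HelixSpec(length=length, origin=origin, axis=axis,
                               phase=40.0 * h))
    return specs


# author numbering of synthetic chains: helix h occupies 100*h + ...
def _author_start(helix: int) -> int:
    return 100 * helix + 1


def build_bundle(layout: list[HelixSpec] | None = None,
                 sequence: str | None = None,
                 receptor_id: str = "syn",
                 entry_id: str = "SYN1",
                 chain_id: str = "A",
                 definition: BundleDefinition = DEFAULT_DEFINITION) -> tuple[ChainModel, ReceptorMap]:
    """Build a synthetic 7TM chain plus the ReceptorMap that addresses it.

    The chain has contiguous author numbering within each helix (helix h
    starting at author residue 100·h+1) and round-trips through
    ``extract_bundle`` to exactly 200 positions.
    """
    layout = layout if layout is not None else default_layout(definition)
    if len(layout) != 7 or tuple(s.length for s in layout) != definition.lengths:
        raise ValueError(f"layout must hold 7 helices of lengths {definition.lengths}")
    if sequence is None:
        sequence = "A" * definition.size
    if len(sequence) != definition.size:
        raise ValueError(f"sequence must have {definition.size} letters")

    residues: list[tuple[ResidueKey, list[AtomRecord]]] = []
    anchors: dict[int, int] = {}
    pos = 0
    for h, spec in enumerate(layout, start=1):
        start_bw = definition.ranges[h - 1][0].index
        start_author = _author_start(h)
        anchors[h] = start_author + (50 - start_bw)
        resnames = [one_to_three(aa) for aa in sequence[pos:pos + spec.length]]
        helix = ideal_helix(spec, with_backbone=True, resnames=resnames)
        for k, res in enumerate(helix):
            key = ResidueKey(chain_id, start_author + k, "", res.resname)
            atoms = [AtomRecord("N", "N", res.n), AtomRecord("CA", "C", res.ca),
                     AtomRecord("C", "C", res.c), AtomRecord("O", "O", res.o)]
            residues.append((key, atoms))
        pos += spec.length
    chain = ChainModel(entry_id, chain_id, 1, residues)
    rmap = ReceptorMap(receptor_id, anchors, source_note="synthetic bundle generator")
    return chain, rmap


def add_ionic_lock_sidechains(chain: ChainModel, rmap: ReceptorMap,
                              distance: float = 3.0,
                              acidic: str = "GLU",
                              definition: BundleDefinition = DEFAULT_DEFINITION) -> ChainModel:
    """Give Arg(3.50) and the residue at 6.30 pseudo side chains a set distance apart.

    The 3.50 residue is renamed ARG and receives NE/NH1/NH2 atoms; the 6.30
    residue is renamed to ``acidic`` ("GLU"/"ASP", or any other name to model
    the no-acidic-partner case, in which event carboxylate atoms are still
    placed so only the residue identity blocks the lock).  Atoms sit on the
    line between the two Cαs so that the minimal N–O separation equals
    ``distance``.
    """
    num_350 = bw_to_author(rmap, BWNumber(3, 50), definition)
    num_630 = bw_to_author(rmap, BWNumber(6, 30), definition)
    r350 = chain.get_residue(num_350)
    r630 = chain.get_residue(num_630)
    if r350 is None or r630 is None:
        raise ValueError("chain lacks residues at 3.50 / 6.30")
    ca_r = next(a.coord for a in r350[1] if a.name == "CA")
    ca_e = next(a.coord for a in r630[1] if a.name == "CA")
    u = ca_e - ca_r
    gap = np.linalg.norm(u)
    u = u / gap
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    # guanidinium N cluster and carboxylate O pair facing each other along u;
    # the NH1–O pair realises the minimum distance exactly
    nh1 = ca_r + u * (gap - distance) / 2.0
    n_atoms = [AtomRecord("NE", "N", nh1 - 1.2 * u),
               AtomRecord("NH1", "N", nh1),
               AtomRecord("NH2", "N", nh1 - 0.6 * u + 1.1 * perp)]
    o_names = ("OE1", "OE2") if acidic != "ASP" else ("OD1", "OD2")
    o1 = nh1 + u * distance
    o_atoms = [AtomRecord(o_names[0], "O", o1),
               AtomRecord(o_names[1], "O", o1 + 0.6 * u - 1.1 * perp)]

    def _swap(res_key: ResidueKey, extra: list[AtomRecord], name: str) -> None:
        for idx, (key, atoms) in enumerate(chain.residues):
            if key == res_key:
                new_key = ResidueKey(key.chain_id, key.author_seq_number,
                                     key.insertion_code, name)
                chain.residues[idx] = (new_key, atoms + extra)
                return

    _swap(r350[0], n_atoms, "ARG")
    _swap(r630[0], o_atoms, acidic)
    return chain


def _helix_author_range(helix: int, rmap: ReceptorMap,
                        definition: BundleDefinition) -> tuple[int, int]:
    start, end = definition.ranges[helix - 1]
    return bw_to_author(rmap, start, definition), bw_to_author(rmap, end, definition)


def perturb(chain: ChainModel, rmap: ReceptorMap, spec: PerturbationSpec,
            definition: BundleDefinition = DEFAULT_DEFINITION) -> ChainModel:
    """Apply a rigid-body displacement to one helix, then Gaussian noise to all atoms.

    Rotation (if any) acts about ``spec.rotation_axis`` through the target
    helix's Cα centroid, followed by ``spec.translation``; afterwards i.i.d.
    noise of width ``sigma`` is added to every atom of the chain.
    Deterministic for a fixed seed.
    """
    lo, hi = _helix_author_range(spec.helix, rmap, definition)
    rng = np.random.default_rng(spec.seed)

    in_helix = lambda key: lo <= key.author_seq_number <= hi
    cas = [atoms for key, atoms in chain.residues if in_helix(key)]
    centroid = np.mean([next(a.coord for a in atoms if a.name == "CA") for atoms in cas], axis=0)

    if spec.rotation_angle != 0.0:
        from scipy.spatial.transform import Rotation
        ax = spec.rotation_axis / np.linalg.norm(spec.rotation_axis)
        R = Rotation.from_rotvec(np.deg2rad(spec.rotation_angle) * ax).as_matrix()
    else:
        R = np.eye(3)

    new_residues = []
    for key, atoms in chain.residues:
        new_atoms = []
        for a in atoms:
            xyz = a.coord.copy()
            if in_helix(key):
                xyz = R @ (xyz - centroid) + centroid + spec.translation
            new_atoms.append(AtomRecord(a.name, a.element, xyz, a.occupancy, a.altloc))
        new_residues.append((key, new_atoms))
    out = ChainModel(chain.entry_id, chain.chain_id, chain.model_index,
                     new_residues, list(chain.het_residues))
    if spec.sigma > 0:
        for _, atoms in out.residues:
            for a in atoms:
                a.coord = a.coord + rng.normal(0.0, spec.sigma, 3)
    return out


def make_ensemble(out_dir: str | Path,
                  n_chains: int,
                  receptor_ids: list[str] | None = None,
                  perturbations: dict[int, PerturbationSpec] | None = None,
                  sigma: float = 0.0,
                  seed: int = 0,
                  sequence: str | None = None,
                  definition: BundleDefinition = DEFAULT_DEFINITION) -> pd.DataFrame:
    """Write an ensemble of synthetic chains: PDB files, maps, ledger, truth table.

    Chain ``i`` (0-based) becomes entry SYN<i> chain A.  ``perturbations``
    maps chain index → PerturbationSpec; every other chain gets only the
    baseline noise ``sigma``.  Per-chain seeds derive from ``seed``.  Returns
    the truth table (also written to ``truth.tsv``).
    """
    if n_chains < 2:
        raise ValueError("an ensemble needs at least 2 chains")
    out_dir = Path(out_dir)
    (out_dir / "maps").mkdir(parents=True, exist_ok=True)
    receptor_ids = receptor_ids or [f"syn{i}" for i in range(n_chains)]
    if len(receptor_ids) != n_chains:
        raise ValueError("receptor_ids must have one entry per chain")
    perturbations = perturbations or {}

    rows = []
    ledger_lines = ["entry_id\tchain_id\treceptor_id\tligand_class\tnotes"]
    maps_written = set()
    for i in range(n_chains):
        chain, rmap = build_bundle(sequence=sequence, receptor_id=receptor_ids[i],
                                   entry_id=f"SYN{i}", definition=definition)
        spec = perturbations.get(i, PerturbationSpec(sigma=sigma))
        spec = replace(spec, sigma=spec.sigma if i in perturbations else sigma,
                       seed=seed + i)
        chain = perturb(chain, rmap, spec, definition)
        write_chain_pdb(chain, out_dir / f"SYN{i}.pdb")
        if receptor_ids[i] not in maps_written:
            rmap.to_file(out_dir / "maps" / f"{receptor_ids[i]}.map")
            maps_written.add(receptor_ids[i])
        ledger_lines.append(f"SYN{i}\tA\t{receptor_ids[i]}\tantagonist\tsynthetic")
        t = spec.translation
        rows.append(dict(entry=f"SYN{i}", chain="A", helix=spec.helix,
                         dx=t[0], dy=t[1], dz=t[2], angle=spec.rotation_angle,
                         sigma=spec.sigma, seed=spec.seed))
    (out_dir / "ledger.tsv").write_text("\n".join(ledger_lines) + "\n")
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth
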