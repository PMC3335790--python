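"""Ballesteros–Weinstein numbering and the 200-residue 7TM bundle.

Class A GPCRs share seven transmembrane helices, each carrying one
universally conserved anchor residue, numbered h.50 (N1.50, D2.50, R3.50,
W4.50, P5.50, P6.50, P7.50).  A position "h.ii" then counts relative to that
anchor.  The bundle analysed throughout this package is a fixed selection of
200 positions:

    helix I   1.35–1.59  (25)        helix V   5.36–5.65  (30)
    helix II  2.38–2.67  (30)        helix VI  6.29–6.60  (32)
    helix III 3.22–3.55  (34)        helix VII 7.32–7.55  (24)
    helix IV  4.39–4.63  (25)

Because every helix range is contiguous in BW space, a per-receptor mapping
to author (PDB) residue numbers is fully determined by the seven anchor
author numbers: author = anchor + (ii − 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import ChainModel, ResidueKey, ca_trace, three_to_one

__all__ = [
    "BWNumber",
    "BundleDefinition",
    "ReceptorMap",
    "Bundle",
    "SectionDefinition",
    "IncompleteBundleError",
    "DEFAULT_DEFINITION",
    "bw_to_author",
    "extract_bundle",
    "serial_of",
    "bw_of",
    "assign_section",
    "section_definition_from_reference",
]

N_POSITIONS = 200
HELIX_LENGTHS = (25, 30, 34, 25, 30, 32, 24)


@dataclass(frozen=True, order=True)
class BWNumber:
    """Generic residue number h.ii (e.g. 3.50 = the DRY arginine)."""

    helix: int
    index: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 7:
            raise ValueError(f"helix must be 1..7, got {self.helix}")

    def __str__(self) -> str:
        return f"{self.helix}.{self.index:02d}"

    @classmethod
    def parse(cls, text: str) -> "BWNumber":
        h, i = text.strip().split(".")
        return cls(int(h), int(i))


@dataclass(frozen=True)
class BundleDefinition:
    """The seven BW helix ranges making up the bundle (inclusive ends)."""

    ranges: tuple[tuple[BWNumber, BWNumber], ...] = tuple(
        (BWNumber(h, s), BWNumber(h, e))
        for h, s, e in [(1, 35, 59), (2, 38, 67), (3, 22, 55),
                        (4, 39, 63), (5, 36, 65), (6, 29, 60), (7, 32, 55)]
    )

    def __post_init__(self) -> None:
        if len(self.ranges) != 7:
            raise ValueError("a bundle definition needs exactly 7 helix ranges")
        for h, (start, end) in enumerate(self.ranges, start=1):
            if start.helix != h or end.helix != h or end.index < start.index:
                raise ValueError(f"bad range for helix {h}: {start}–{end}")

    def helix_length(self, helix: int) -> int:
        start, end = self.ranges[helix - 1]
        return end.index - start.index + 1

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(self.helix_length(h) for h in range(1, 8))

    @property
    def size(self) -> int:
        return sum(self.lengths)

    def positions(self) -> list[BWNumber]:
        """All bundle positions in serial order (helix I→VII, BW ascending)."""
        out = []
        for start, end in self.ranges:
            out.extend(BWNumber(start.helix, i) for i in range(start.index, end.index + 1))
        return out

    def contains(self, bw: BWNumber) -> bool:
        start, end = self.ranges[bw.helix - 1]
        return start.index <= bw.index <= end.index

    def helix_serial_range(self, helix: int) -> range:
        """Serial positions (0-based, half-open) occupied by one helix."""
        offset = sum(self.lengths[: helix - 1])
        return range(offset, offset + self.helix_length(helix))


DEFAULT_DEFINITION = BundleDefinition()
assert DEFAULT_DEFINITION.size == N_POSITIONS


def serial_of(bw: BWNumber, definition: BundleDefinition = DEFAULT_DEFINITION) -> int:
    """Serial index 0–199 of a BW position within the bundle."""
    if not definition.contains(bw):
        raise ValueError(f"{bw} is outside the bundle definition")
    start, _ = definition.ranges[bw.helix - 1]
    return sum(definition.lengths[: bw.helix - 1]) + (bw.index - start.index)


def bw_of(serial: int, definition: BundleDefinition = DEFAULT_DEFINITION) -> BWNumber:
    """Inverse of :func:`serial_of`."""
    if not 0 <= serial < definition.size:
        raise ValueError(f"serial {serial} outside 0..{definition.size - 1}")
    for h in range(1, 8):
        r = definition.helix_serial_range(h)
        if serial in r:
            start, _ = definition.ranges[h - 1]
            return BWNumber(h, start.index + serial - r.start)
    raise AssertionError("unreachable")


@dataclass
class ReceptorMap:
    """Per-receptor anchors: author residue number of each helix's .50 position."""

    receptor_id: str
    anchors: dict[int, int]
    source_note: str = ""

    def __post_init__(self) -> None:
        if set(self.anchors) != set(range(1, 8)):
            raise ValueError("a receptor map needs exactly the 7 anchors 1.50..7.50")

    @classmethod
    def from_file(cls, path: str | Path, receptor_id: str | None = None) -> "ReceptorMap":
        """Read lines of the form ``helix3.50 = 135``; ``#`` starts a comment."""
        path = Path(path)
        anchors: dict[int, int] = {}
        note = ""
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                note += line.lstrip("# ") + " "
                continue
            key, _, val = line.partition("=")
            key = key.strip().lower()
            if not key.startswith("helix") or not key.endswith(".50"):
                raise ValueError(f"{path}: bad map line {line!r}")
            anchors[int(key[5:-3])] = int(val)
        return cls(receptor_id or path.stem, anchors, note.strip())

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"# {self.source_note}"] if self.source_note else []
        lines += [f"helix{h}.50 = {self.anchors[h]}" for h in range(1, 8)]
        path.write_text("\n".join(lines) + "\n")
        return path


def bw_to_author(rmap: ReceptorMap, bw: BWNumber,
                 definition: BundleDefinition = DEFAULT_DEFINITION) -> int:
    """Author residue number of a BW position (anchor + constant offset)."""
    if not definition.contains(bw):
        raise ValueError(f"{bw} is outside the bundle definition")
    return rmap.anchors[bw.helix] + (bw.index - 50)


def author_to_bw(rmap: ReceptorMap, author_number: int,
                 definition: BundleDefinition = DEFAULT_DEFINITION) -> BWNumber | None:
    """BW position whose mapped author number matches, or None if outside the bundle."""
    for bw in definition.positions():
        if bw_to_author(rmap, bw, definition) == author_number:
            return bw
    return None


class IncompleteBundleError(ValueError):
    """Chain lacks a Cα at one or more mapped bundle positions."""

    def __init__(self, entry_id: str, chain_id: str, missing: list[BWNumber]):
        self.missing = missing
        shown = ", ".join(str(m) for m in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        super().__init__(f"incomplete bundle {entry_id}:{chain_id}; missing {shown}{more}")


@dataclass
class Bundle:
    """The 200-residue Cα trace of one chain, in BW serial order."""

    receptor_id: str
    entry_id: str
    chain_id: str
    state: str  # "inactivated" | "activated"
    bw: list[BWNumber]
    author_keys: list[ResidueKey]
    coords: np.ndarray  # (200, 3) Cα, Å
    sequence: str       # 200 one-letter codes
    definition: BundleDefinition = field(default=DEFAULT_DEFINITION, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.definition.size
        if not (len(self.bw) == len(self.author_keys) == len(self.sequence) == n
                and self.coords.shape == (n, 3)):
            raise ValueError(f"a bundle must hold exactly {n} positions")

    @property
    def label(self) -> str:
        return f"{self.entry_id}-{self.chain_id}"

    def helix_coords(self, helix: int) -> np.ndarray:
        r = self.definition.helix_serial_range(helix)
        return self.coords[r.start:r.stop]

    def serial_of(self, bw: BWNumber) -> int:
        return serial_of(bw, self.definition)

    def transformed(self, superposition) -> "Bundle":
        """Copy with coordinates moved by a Superposition."""
        return Bundle(self.receptor_id, self.entry_id, self.chain_id, self.state,
                      list(self.bw), list(self.author_keys),
                      superposition.apply(self.coords), self.sequence, self.definition)


def extract_bundle(chain: ChainModel, rmap: ReceptorMap,
                   state: str = "inactivated",
                   definition: BundleDefinition = DEFAULT_DEFINITION,
                   receptor_id: str | None = None) -> Bundle:
    """Pull the 200 bundle Cαs out of a chain using the receptor's BW map.

    Chains missing any mapped position are rejected with
    :class:`IncompleteBundleError` — mirroring the exclusion of chains that
    resolve fewer than the full 200 bundle residues.
    """
    if state not in ("inactivated", "activated"):
        raise ValueError(f"state must be 'inactivated' or 'activated', got {state!r}")
    trace = {k.author_seq_number: (k, xyz) for k, xyz in ca_trace(chain)
             if not k.insertion_code}
    bws, keys, coords, seq, missing = [], [], [], [], []
    for bw in definition.positions():
        num = bw_to_author(rmap, bw, definition)
        hit = trace.get(num)
        if hit is None:
            missing.append(bw)
            continue
        key, xyz = hit
        bws.append(bw)
        keys.append(key)
        coords.append(xyz)
        seq.append(three_to_one(key.residue_name))
    if missing:
        raise IncompleteBundleError(chain.entry_id, chain.chain_id, missing)
    return Bundle(receptor_id or rmap.receptor_id, chain.entry_id, chain.chain_id,
                  state, bws, keys, np.array(coords), "".join(seq), definition)


@dataclass
class SectionDefinition:
    """Total assignment of the 200 BW positions to 5 membrane slabs.

    Section 1 is the extracellular surface layer (ligand entry), section 5
    the cytoplasmic surface layer (G-protein side, D/ERY motif).
    """

    labels: dict[BWNumber, int]
    description: str = ""

    def __post_init__(self) -> None:
        bad = {bw: s for bw, s in self.labels.items() if not 1 <= s <= 5}
        if bad:
            raise ValueError(f"section labels must be 1..5; bad: {bad}")

    def section(self, bw: BWNumber) -> int:
        return self.labels[bw]

    @classmethod
    def from_file(cls, path: str | Path) -> "SectionDefinition":
        labels: dict[BWNumber, int] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            bw, _, sec = line.partition("=")
            labels[BWNumber.parse(bw)] = int(sec)
        return cls(labels, description=f"read from {path}")

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{bw} = {sec}" for bw, sec in sorted(self.labels.items())]
        path.write_text("\n".join(lines) + "\n")
        return path


def assign_section(bw: BWNumber, sections: SectionDefinition) -> int:
    """Section (1–5) of a bundle position."""
    return sections.section(bw)


def section_definition_from_reference(reference: Bundle) -> SectionDefinition:
    """Build the default 5-section slab partition from a reference bundle.

    Helix IV sits nearly perpendicular to the membrane plane, so its 25
    bundle residues are cut into five consecutive 5-residue blocks (block 1
    at the extracellular end, 4.59–4.63); every other position joins the
    section whose helix IV block is nearest along the helix IV axis.  Each
    slab comes out roughly 7.5 Å thick.
    """
    definition = reference.definition
    h4 = reference.helix_coords(4)
    centroid = h4.mean(axis=0)
    # principal axis of helix IV, oriented cytoplasmic (4.39) -> extracellular (4.63)
    _, _, vt = np.linalg.svd(h4 - centroid)
    axis = vt[0]
    if axis @ (h4[-1] - h4[0]) < 0:
        axis = -axis
    z = (reference.coords - centroid) @ axis  # +z toward extracellular

    h4_range = definition.helix_serial_range(4)
    h4_z = z[h4_range.start:h4_range.stop]
    # five consecutive 5-residue blocks along helix IV; highest mean z = section 1
    n_blocks = 5
    block = definition.helix_length(4) // n_blocks
    block_z = np.array([h4_z[i * block:(i + 1) * block].mean() for i in range(n_blocks)])
    order = np.argsort(block_z)[::-1]  # extracellular first
    section_z = block_z[order]

    labels = {}
    for serial, bw in enumerate(definition.positions()):
        labels[bw] = int(np.argmin(np.abs(section_z - z[serial]))) + 1
    return SectionDefinition(labels, description=f"z-slab partition from {reference.label}")
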