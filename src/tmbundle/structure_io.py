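"""Reading structure files and exposing chains as clean coordinate containers.

Parsing of PDB / mmCIF is delegated to :mod:`gemmi`; this module converts
gemmi's hierarchy into small immutable-ish containers (:class:`AtomRecord`,
:class:`ResidueKey`, :class:`ChainModel`) that the rest of the package works
with.  Only model 1 of multi-model files is used unless explicitly requested:
the analyses here target crystallographic structures.
"""

from __future__ import annotations

import logging
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "ChainModel",
    "StructureError",
    "ChainNotFoundError",
    "read_structure",
    "select_chain",
    "ca_trace",
    "write_chain_pdb",
    "fetch_entry",
]


class StructureError(ValueError):
    """Raised for unreadable, empty or otherwise unusable structure input."""


class ChainNotFoundError(KeyError):
    """Requested (entry, chain) pair is absent; message lists what exists."""


@dataclass
class AtomRecord:
    """One atom: name, element, coordinates (Å), occupancy and altloc."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class ResidueKey:
    """Author-numbering identity of a residue within a chain."""

    chain_id: str
    author_seq_number: int
    insertion_code: str = ""
    residue_name: str = "UNK"


@dataclass
class ChainModel:
    """One polypeptide chain of one model: ordered residues with their atoms.

    ``residues`` holds the polymer (amino-acid) residues in author order;
    heteroatom residues (ligands, waters, ions) are retained separately in
    ``het_residues`` so they never enter the Cα-level analyses by accident.
    """

    entry_id: str
    chain_id: str
    model_index: int
    residues: list[tuple[ResidueKey, list[AtomRecord]]]
    het_residues: list[tuple[ResidueKey, list[AtomRecord]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_index(self) -> dict[tuple[int, str], tuple[ResidueKey, list[AtomRecord]]]:
        """Map (author number, insertion code) -> (key, atoms)."""
        return {(k.author_seq_number, k.insertion_code): (k, atoms) for k, atoms in self.residues}

    def get_residue(self, author_number: int, icode: str = "") -> tuple[ResidueKey, list[AtomRecord]] | None:
        for key, atoms in self.residues:
            if key.author_seq_number == author_number and key.insertion_code == icode:
                return key, atoms
        return None


# Selenomethionine is read as MET for sequence purposes.
_RESNAME_ALIASES = {"MSE": "MET"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def three_to_one(resname: str) -> str:
    """Translate a 3-letter residue code to 1-letter; unknown codes become X."""
    return _THREE_TO_ONE.get(_RESNAME_ALIASES.get(resname, resname), "X")


def one_to_three(aa: str) -> str:
    return _ONE_TO_THREE.get(aa.upper(), "UNK")


def _is_amino(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # unannotated residues with full backbone are treated as polymer
    names = {a.name for a in res}
    return {"N", "CA", "C"} <= names


def read_structure(path: str | Path, fmt: str | None = None, all_models: bool = False) -> list[ChainModel]:
    """Read a PDB or mmCIF file into one :class:`ChainModel` per chain.

    ``fmt`` may be ``"pdb"`` or ``"mmcif"``; by default it is detected from
    the file contents/extension.  Only model 1 is returned unless
    ``all_models`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
            if fmt not in fmt_map:
                raise StructureError(f"unknown format {fmt!r}; expected 'pdb' or 'mmcif'")
            st = gemmi.read_structure(str(path), format=fmt_map[fmt])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    # HEADER idCode is capped at 4 characters; the file stem may carry the
    # full id (e.g. synthetic SYN12.pdb), so prefer the stem when it extends
    # the recorded code
    stem = path.stem.upper()
    name = (st.info["_entry.id"] if "_entry.id" in st.info else st.name).strip().upper()
    entry_id = stem if (not name or stem.startswith(name)) else name
    chains: list[ChainModel] = []
    for mi, model in enumerate(st, start=1):
        if not all_models and mi > 1:
            break
        for chain in model:
            residues: list[tuple[ResidueKey, list[AtomRecord]]] = []
            het: list[tuple[ResidueKey, list[AtomRecord]]] = []
            for res in chain:
                key = ResidueKey(
                    chain_id=chain.name,
                    author_seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or " ").strip(),
                    residue_name=_RESNAME_ALIASES.get(res.name, res.name),
                )
                atoms = [
                    AtomRecord(
                        name=a.name,
                        element=a.element.name,
                        coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=min(max(a.occ, 0.0), 1.0),
                        altloc=(a.altloc or "").strip(),
                    )
                    for a in res
                ]
                (residues if _is_amino(res) else het).append((key, atoms))
            if residues:
                cm = ChainModel(entry_id, chain.name, mi, residues, het)
                n_ca = len(ca_trace(cm))
                log.info("%s %s %d %d", entry_id, chain.name, len(residues), n_ca)
                chains.append(cm)
    if not chains:
        raise StructureError(f"{path}: no polymer chains")
    return chains


def select_chain(chains: list[ChainModel], entry_id: str, chain_id: str) -> ChainModel:
    """Pick the chain with the given entry and chain id."""
    for c in chains:
        if c.entry_id.upper() == entry_id.upper() and c.chain_id == chain_id:
            return c
    avail = ", ".join(f"{c.entry_id}:{c.chain_id}" for c in chains)
    raise ChainNotFoundError(f"chain not found: {entry_id}:{chain_id} (available: {avail})")


def _resolve_altloc(atoms: list[AtomRecord], name: str) -> AtomRecord | None:
    """Pick one atom of the given name: highest occupancy, tie -> altloc 'A', then blank."""
    cands = [a for a in atoms if a.name == name]
    if not cands:
        return None
    if len(cands) == 1:
        return cands[0]

    def rank(a: AtomRecord) -> tuple:
        return (a.occupancy, a.altloc == "A", a.altloc == "")

    return max(cands, key=rank)


def ca_trace(chain: ChainModel) -> list[tuple[ResidueKey, np.ndarray]]:
    """Ordered (key, Cα coordinate) for every residue that has a Cα.

    Residues lacking a Cα are omitted (and logged); altloc duplicates are
    resolved by occupancy.
    """
    out: list[tuple[ResidueKey, np.ndarray]] = []
    for key, atoms in chain.residues:
        ca = _resolve_altloc(atoms, "CA")
        if ca is None:
            log.debug("%s %s %d%s: no CA, omitted", chain.entry_id, key.chain_id,
                      key.author_seq_number, key.insertion_code)
            continue
        out.append((key, ca.coord))
    return out


def resolved_atoms(atoms: list[AtomRecord]) -> dict[str, np.ndarray]:
    """All atoms of a residue keyed by name, altloc-resolved."""
    names = {a.name for a in atoms}
    return {n: _resolve_altloc(atoms, n).coord for n in names}


def write_chain_pdb(chain: ChainModel, path: str | Path) -> Path:
    """Write a ChainModel back out as fixed-column PDB (via gemmi)."""
    st = gemmi.Structure()
    st.name = chain.entry_id
    model = gemmi.Model(1)
    gchain = gemmi.Chain(chain.chain_id)
    for key, atoms in list(chain.residues) + list(chain.het_residues):
        res = gemmi.Residue()
        res.name = key.residue_name
        res.seqid = gemmi.SeqId(key.author_seq_number, key.insertion_code or " ")
        for a in atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coord)
            at.occ = a.occupancy
            at.altloc = a.altloc or "\0"
            res.add_atom(at)
        gchain.add_residue(res)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))
    # gemmi does not emit a HEADER record for a bare structure; add one so the
    # entry id survives a round trip (idCode in columns 63-66)
    body = path.read_text()
    if not body.startswith("HEADER"):
        header = f"HEADER    MEMBRANE PROTEIN                        01-JAN-00   {chain.entry_id[:4].upper():<4}\n"
        path.write_text(header + body)
    return path


_ACCESSION_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
_PDB_URL = "https://files.rcsb.org/download/{acc}.pdb"


def fetch_entry(accession: str, cache_dir: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry once into ``cache_dir``; return the cached path.

    Purely a convenience — every analysis in this package also runs on local
    files and on synthetic structures, without network access.
    """
    if not _ACCESSION_RE.match(accession or ""):
        raise ValueError(f"malformed PDB accession: {accession!r}")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{accession.upper()}.pdb"
    if dest.exists() and dest.stat().st_size > 0:
        return dest
    url = _PDB_URL.format(acc=accession.upper())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except OSError as exc:
        raise StructureError(f"fetch failed for {accession}: {exc}") from exc
    dest.write_bytes(data)
    return dest
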