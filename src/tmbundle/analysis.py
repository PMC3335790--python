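"""Pipeline statistics over 7TM bundles.

Chain classification by ligand class, pairwise rmsd grids averaged by
receptor pair, per-position Cα deviation profiles in a common reference
frame, five-slab sectional rmsds, isolated-helix rigid-body comparison,
ionic-lock census, bundle sequence identity and outlier screening.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .numbering import (DEFAULT_DEFINITION, Bundle, BundleDefinition, BWNumber,
                        ReceptorMap, SectionDefinition, bw_to_author)
from .structure_io import ChainModel, resolved_atoms
from .superpose import kabsch_fit, per_position_deviation, rmsd_between, ssm_fit

log = logging.getLogger(__name__)

__all__ = [
    "classify_chain",
    "fit_all_to_reference",
    "pairwise_rmsd_matrix",
    "average_by_receptor_pair",
    "ReceptorPairGrid",
    "DeviationProfile",
    "deviation_profile",
    "sectional_rmsd",
    "isolated_helix_comparison",
    "IonicLockState",
    "ionic_lock_state",
    "sequence_identity",
    "outlier_screen",
]

# state is a pure function of the bound-ligand class
_STATE_OF_LIGAND = {
    "antagonist": "inactivated",
    "inverse_agonist": "inactivated",
    "agonist": "activated",
    "ligand_free": "activated",
}


def classify_chain(ligand_class: str) -> str:
    """Map a ligand class to the chain state (inactivated/activated).

    Antagonist- and inverse-agonist-bound chains count as inactivated;
    agonist-bound and ligand-free chains as activated.  Unknown classes are
    an error, never a silent default.
    """
    try:
        return _STATE_OF_LIGAND[ligand_class.strip().lower().replace("-", "_")]
    except KeyError:
        raise ValueError(
            f"unknown ligand class {ligand_class!r}; expected one of "
            f"{sorted(_STATE_OF_LIGAND)}") from None


def fit_all_to_reference(bundles: list[Bundle], reference: Bundle,
                         method: str = "ssm") -> list[Bundle]:
    """Express every bundle in the reference chain's frame (one fit each)."""
    out = []
    for b in bundles:
        if b.label == reference.label:
            out.append(b)
            continue
        sup = ssm_fit(b, reference) if method == "ssm" else kabsch_fit(b.coords, reference.coords)
        if not getattr(sup, "converged", True):
            log.warning("SSM fit %s -> %s did not converge", b.label, reference.label)
        out.append(b.transformed(sup))
    return out


def pairwise_rmsd_matrix(bundles: list[Bundle], method: str = "ssm") -> pd.DataFrame:
    """Symmetric matrix of pairwise bundle rmsds (diagonal 0)."""
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles")
    labels = [b.label for b in bundles]
    n = len(bundles)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = rmsd_between(bundles[i], bundles[j], method=method)
    return pd.DataFrame(m, index=labels, columns=labels)


@dataclass
class ReceptorPairGrid:
    """Per-receptor-pair mean/sd/count of rmsds plus mean sequence identity."""

    receptors: list[str]
    mean: pd.DataFrame
    sd: pd.DataFrame
    n_values: pd.DataFrame
    identity: pd.DataFrame | None = None

    def n_groups(self) -> int:
        """Number of realizable pair groups (cross pairs + self pairs with ≥2 chains)."""
        count = 0
        for i, r in enumerate(self.receptors):
            for s in self.receptors[i:]:
                if not np.isnan(self.mean.loc[r, s]):
                    count += 1
        return count


def average_by_receptor_pair(matrix: pd.DataFrame, receptor_of: dict[str, str],
                             identities: pd.DataFrame | None = None) -> ReceptorPairGrid:
    """Group a chain-level pairwise matrix into receptor pairs and average.

    For receptors r, s with n_r and n_s chains the group holds n_r·n_s
    values (r≠s) or n_r(n_r−1)/2 (r=s); self pairs exist only for receptors
    with at least two chains.  Averages are arithmetic means of the pair
    rmsds.
    """
    missing = [l for l in matrix.index if l not in receptor_of]
    if missing:
        raise ValueError(f"unlabeled chains: {missing}")
    receptors = list(dict.fromkeys(receptor_of[l] for l in matrix.index))
    shape = (len(receptors), len(receptors))
    mean = pd.DataFrame(np.full(shape, np.nan), index=receptors, columns=receptors)
    sd = pd.DataFrame(np.full(shape, np.nan), index=receptors, columns=receptors)
    nv = pd.DataFrame(np.zeros(shape, dtype=int), index=receptors, columns=receptors)
    ident = pd.DataFrame(np.full(shape, np.nan), index=receptors, columns=receptors)

    groups: dict[tuple[str, str], list[float]] = {}
    id_groups: dict[tuple[str, str], list[float]] = {}
    labels = list(matrix.index)
    for a, b in itertools.combinations(labels, 2):
        r, s = sorted((receptor_of[a], receptor_of[b]))
        groups.setdefault((r, s), []).append(float(matrix.loc[a, b]))
        if identities is not None:
            id_groups.setdefault((r, s), []).append(float(identities.loc[a, b]))

    for (r, s), vals in groups.items():
        mean.loc[r, s] = mean.loc[s, r] = float(np.mean(vals))
        sd.loc[r, s] = sd.loc[s, r] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        nv.loc[r, s] = nv.loc[s, r] = len(vals)
    for (r, s), vals in id_groups.items():
        ident.loc[r, s] = ident.loc[s, r] = float(np.mean(vals))
    return ReceptorPairGrid(receptors, mean, sd, nv,
                            ident if identities is not None else None)


@dataclass
class DeviationProfile:
    """Per-position Cα–Cα deviations averaged over chain pairs."""

    values: np.ndarray            # (200,), Å
    n_pairs: int
    counts: np.ndarray = field(default=None)  # contributing pairs per position

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("deviations must be non-negative")
        if self.counts is None:
            self.counts = np.full(self.values.shape, self.n_pairs, dtype=int)


def deviation_profile(bundles: list[Bundle]) -> DeviationProfile:
    """Average per-position deviation over all chain pairs, in a shared frame.

    The bundles must already be expressed in the common reference frame
    (see :func:`fit_all_to_reference`); with 9 chains this averages
    C(9,2) = 36 pairwise deviation curves position by position.
    """
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles for a deviation profile")
    n_pos = bundles[0].definition.size
    acc = np.zeros(n_pos)
    n_pairs = 0
    for a, b in itertools.combinations(bundles, 2):
        acc += per_position_deviation(a, b, frame="common_reference")
        n_pairs += 1
    return DeviationProfile(acc / n_pairs, n_pairs)


def sectional_rmsd(a: Bundle, b: Bundle, sections: SectionDefinition,
                   method: str = "ssm") -> np.ndarray:
    """Rmsd of each of the 5 membrane sections, in the whole-bundle frame.

    The bundles are superposed once over all 200 positions; the sectional
    values are then computed on the fitted coordinates without refitting, so
    the position-count-weighted mean of the squared sectional rmsds equals
    the squared all-200 rmsd exactly.
    """
    sup = ssm_fit(b, a) if method == "ssm" else kabsch_fit(b.coords, a.coords)
    moved = sup.apply(b.coords)
    d2 = np.sum((a.coords - moved) ** 2, axis=1)
    labels = np.array([sections.section(bw) for bw in a.bw])
    return np.array([np.sqrt(d2[labels == s].mean()) for s in range(1, 6)])


def isolated_helix_comparison(bundles: list[Bundle], helix: int,
                              reference: Bundle) -> pd.DataFrame:
    """Contrast in-bundle displacement of one helix with its isolated-fit rmsd.

    For each chain (already in the reference's common frame) three numbers
    are reported for the chosen helix: ``bundle_frame_deviation`` — mean Cα
    deviation from the reference helix in the shared frame;
    ``net_displacement`` — the norm of the mean deviation vector after
    re-expressing the chain in a frame fitted on the other six helices only
    (so the estimate of a rigid shift is not diluted by the displaced helix
    taking part in the fit); and ``isolated_rmsd`` — rmsd after fitting the
    helix alone onto the reference helix.  A helix that is rigidly displaced
    but internally unchanged shows high deviation with a near-zero isolated
    rmsd.
    """
    if not 1 <= helix <= 7:
        raise ValueError(f"helix must be 1..7, got {helix}")
    definition = reference.definition
    r = definition.helix_serial_range(helix)
    in_helix = np.zeros(definition.size, dtype=bool)
    in_helix[r.start:r.stop] = True
    ref = reference.helix_coords(helix)
    rows = []
    for b in bundles:
        xyz = b.helix_coords(helix)
        delta = xyz - ref
        if b.label == reference.label:
            net = 0.0
        else:
            six = kabsch_fit(b.coords[~in_helix], reference.coords[~in_helix])
            net = float(np.linalg.norm((six.apply(b.coords[in_helix]) - ref).mean(axis=0)))
        rows.append(dict(
            label=b.label,
            receptor_id=b.receptor_id,
            bundle_frame_deviation=float(np.linalg.norm(delta, axis=1).mean()),
            net_displacement=net,
            isolated_rmsd=kabsch_fit(xyz, ref).rmsd,
        ))
    return pd.DataFrame(rows).set_index("label")


_ACIDIC_O = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
_ARG_N = ("NE", "NH1", "NH2")


@dataclass
class IonicLockState:
    """Salt-bridge status between Arg(3.50) and the residue at 6.30."""

    status: str  # locked | unlocked | no_acidic_partner | indeterminate
    min_distance: float | None = None
    residue_350: str = ""
    residue_630: str = ""


def ionic_lock_state(chain: ChainModel, rmap: ReceptorMap, cutoff: float = 4.0,
                     definition: BundleDefinition = DEFAULT_DEFINITION) -> IonicLockState:
    """Detect the ionic lock: Arg(3.50) side-chain N to Glu/Asp(6.30) carboxylate O.

    ``locked`` iff 6.30 is Glu or Asp and the minimal N–O distance over
    NE/NH1/NH2 × OE1/OE2 (or OD1/OD2) is ≤ ``cutoff`` (default 4.0 Å, the
    conventional salt-bridge threshold).  ``no_acidic_partner`` when 6.30 is
    neither; ``indeterminate`` when side-chain atoms are unresolved.  A
    non-Arg 3.50 is reported unlocked with a warning (the position is highly
    conserved but not universal).
    """
    res350 = chain.get_residue(bw_to_author(rmap, BWNumber(3, 50), definition))
    res630 = chain.get_residue(bw_to_author(rmap, BWNumber(6, 30), definition))
    if res350 is None or res630 is None:
        raise ValueError("residues at 3.50 / 6.30 not resolvable in this chain")
    key350, atoms350 = res350
    key630, atoms630 = res630

    if key350.residue_name != "ARG":
        log.warning("%s: residue at 3.50 is %s, not Arg — reported unlocked",
                    chain.entry_id, key350.residue_name)
        return IonicLockState("unlocked", None, key350.residue_name, key630.residue_name)
    if key630.residue_name not in _ACIDIC_O:
        return IonicLockState("no_acidic_partner", None,
                              key350.residue_name, key630.residue_name)

    coords350 = resolved_atoms(atoms350)
    coords630 = resolved_atoms(atoms630)
    n_atoms = [coords350[n] for n in _ARG_N if n in coords350]
    o_atoms = [coords630[o] for o in _ACIDIC_O[key630.residue_name] if o in coords630]
    if not n_atoms or not o_atoms:
        return IonicLockState("indeterminate", None,
                              key350.residue_name, key630.residue_name)
    dmin = min(float(np.linalg.norm(n - o)) for n in n_atoms for o in o_atoms)
    status = "locked" if dmin <= cutoff else "unlocked"
    return IonicLockState(status, dmin, key350.residue_name, key630.residue_name)


def sequence_identity(a: Bundle, b: Bundle) -> float:
    """Percent identity over the 200 aligned BW positions (1 decimal)."""
    matches = sum(x == y for x, y in zip(a.sequence, b.sequence))
    return round(100.0 * matches / len(a.sequence), 1)


def outlier_screen(bundles: list[Bundle], region: tuple[BWNumber, BWNumber],
                   threshold: float = 2.0, method: str = "ssm") -> list[str]:
    """Flag chains of one receptor deviating from the medoid within a BW region.

    The medoid chain minimises the summed whole-bundle rmsd to the others;
    every other chain is superposed onto it (whole bundle) and flagged when
    its mean Cα deviation inside ``region`` exceeds ``threshold`` Å.  With
    threshold 0 every non-medoid chain is flagged (degenerate but valid).
    """
    if len(bundles) < 2:
        raise ValueError("need at least 2 chains to screen for outliers")
    definition = bundles[0].definition
    lo, hi = region
    serials = [s for s, bw in enumerate(definition.positions())
               if bw.helix == lo.helix and lo.index <= bw.index <= hi.index]
    if not serials:
        raise ValueError(f"empty region {lo}–{hi}")

    m = pairwise_rmsd_matrix(bundles, method=method)
    medoid_idx = int(np.argmin(m.values.sum(axis=0)))
    medoid = bundles[medoid_idx]
    flagged = []
    for i, b in enumerate(bundles):
        if i == medoid_idx:
            continue
        sup = ssm_fit(b, medoid) if method == "ssm" else kabsch_fit(b.coords, medoid.coords)
        moved = sup.apply(b.coords)
        dev = np.linalg.norm(moved[serials] - medoid.coords[serials], axis=1).mean()
        if dev > threshold:
            flagged.append(b.label)
    return flagged
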