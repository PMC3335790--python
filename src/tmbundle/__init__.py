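"""tmbundle — comparative analysis of GPCR heptahelical transmembrane bundles.

Extracts a fixed 200-residue seven-helix bundle from receptor structures via
Ballesteros–Weinstein numbering, superposes bundles by secondary-structure
matching onto a common reference, and computes pairwise rmsd/identity grids,
per-position Cα deviation profiles, five-slab sectional rmsds, isolated-helix
rigid-body comparisons and an ionic-lock census — with a synthetic bundle
generator so the whole pipeline runs without downloads.
"""

from importlib import resources as _resources
from pathlib import Path as _Path

from .numbering import (BWNumber, Bundle, BundleDefinition, ReceptorMap,
                        SectionDefinition, DEFAULT_DEFINITION, bw_to_author,
                        extract_bundle, serial_of, bw_of, assign_section,
                        section_definition_from_reference)
from .structure_io import (AtomRecord, ChainModel, ResidueKey, read_structure,
                           select_chain, ca_trace, fetch_entry)
from .superpose import (Superposition, kabsch_fit, ssm_fit,
                        per_position_deviation, rmsd_between)
from .analysis import (classify_chain, pairwise_rmsd_matrix,
                       average_by_receptor_pair, deviation_profile,
                       sectional_rmsd, isolated_helix_comparison,
                       ionic_lock_state, sequence_identity, outlier_screen,
                       fit_all_to_reference)

__version__ = "0.1.0"


def data_path(*parts: str) -> _Path:
    """Path to a shipped data file (receptor maps, chain ledger)."""
    return _Path(str(_resources.files("tmbundle") / "data")).joinpath(*parts)
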