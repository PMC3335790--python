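"""End-to-end pipeline: read → extract → classify → superpose → report.

Consumes a chain ledger (TSV: entry_id, chain_id, receptor_id, ligand_class,
notes), a directory of receptor maps and a directory of structure files;
produces the Table-1-style receptor-pair grid, the 200-position deviation
profile, sectional rmsds, the isolated-helix report and the ionic-lock
census, as TSV files plus one machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, superpose
from .numbering import (DEFAULT_DEFINITION, Bundle, BundleDefinition,
                        IncompleteBundleError, ReceptorMap, SectionDefinition,
                        section_definition_from_reference)
from .structure_io import read_structure, select_chain

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_grid", "write_profile",
           "load_ledger", "load_maps"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (echoed into the output directory)."""

    ledger_path: Path
    map_dir: Path
    structure_dir: Path
    output_dir: Path
    reference_label: str = "2RH1-A"
    method: str = "ssm"
    ionic_lock_cutoff: float = 4.0
    section_config: Path | None = None
    helix_of_interest: int = 3
    state: str = "inactivated"
    seed: int = 0
    definition: BundleDefinition = field(default=DEFAULT_DEFINITION, repr=False)

    def __post_init__(self) -> None:
        for name in ("ledger_path", "map_dir", "structure_dir"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        self.output_dir = Path(self.output_dir)
        if self.section_config is not None:
            self.section_config = Path(self.section_config)
            if not self.section_config.exists():
                raise FileNotFoundError(f"section_config: {self.section_config}")

    def echo(self) -> str:
        pairs = [(k, getattr(self, k)) for k in
                 ("ledger_path", "map_dir", "structure_dir", "output_dir",
                  "reference_label", "method", "ionic_lock_cutoff",
                  "section_config", "helix_of_interest", "state", "seed")]
        return "\n".join(f"{k} = {v}" for k, v in pairs) + "\n"


def load_ledger(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"entry_id", "chain_id", "receptor_id", "ligand_class"}
    if not required <= set(df.columns):
        raise ValueError(f"ledger must have columns {sorted(required)}")
    return df


def load_maps(map_dir: str | Path) -> dict[str, ReceptorMap]:
    maps = {}
    for path in sorted(Path(map_dir).glob("*.map")):
        rmap = ReceptorMap.from_file(path)
        maps[rmap.receptor_id] = rmap
    if not maps:
        raise ValueError(f"no .map files in {map_dir}")
    return maps


def _stage(name: str, **counts) -> None:
    log.info("stage %-12s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the JSON-ready summary dict.

    Any stage failure aborts with a stage-named error and removes partial
    outputs.  Reruns with identical config and inputs produce byte-identical
    TSVs.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise


def _run(config: RunConfig) -> dict:
    out = config.output_dir
    (out / "config.txt").write_text(config.echo())
    ledger = load_ledger(config.ledger_path)
    maps = load_maps(config.map_dir)

    # classify
    try:
        ledger["state"] = [analysis.classify_chain(c) for c in ledger["ligand_class"]]
    except ValueError as exc:
        raise RuntimeError(f"stage classify: {exc}") from exc
    _stage("classify", chains=len(ledger),
           inactivated=int((ledger.state == "inactivated").sum()),
           activated=int((ledger.state == "activated").sum()))
    ledger = ledger[ledger.state == config.state]

    # read + extract
    bundles: list[Bundle] = []
    chains_map = {}
    excluded: list[dict] = []
    for _, row in ledger.iterrows():
        path = None
        for ext in (".pdb", ".cif", ".ent"):
            cand = config.structure_dir / f"{row.entry_id}{ext}"
            if cand.exists():
                path = cand
                break
        if path is None:
            raise RuntimeError(f"stage read: no structure file for {row.entry_id} "
                               f"in {config.structure_dir}")
        try:
            chain = select_chain(read_structure(path), row.entry_id, row.chain_id)
        except Exception as exc:
            raise RuntimeError(f"stage read: {exc}") from exc
        rmap = maps.get(row.receptor_id)
        if rmap is None:
            excluded.append(dict(label=f"{row.entry_id}-{row.chain_id}", reason="unmapped"))
            continue
        from .numbering import extract_bundle
        try:
            bundle = extract_bundle(chain, rmap, state=row.state,
                                    definition=config.definition)
        except IncompleteBundleError as exc:
            excluded.append(dict(label=f"{row.entry_id}-{row.chain_id}",
                                 reason=f"incomplete: {exc}"))
            continue
        bundles.append(bundle)
        chains_map[bundle.label] = chain
    _stage("extract", read=len(ledger), extracted=len(bundles), excluded=len(excluded))
    if len(bundles) < 2:
        raise RuntimeError("stage extract: fewer than 2 complete bundles")

    # superpose onto the common reference
    ref = next((b for b in bundles if b.label == config.reference_label), None)
    if ref is None:
        ref = bundles[0]
        log.warning("reference %s not among bundles; using %s",
                    config.reference_label, ref.label)
    fitted = analysis.fit_all_to_reference(bundles, ref, method=config.method)
    _stage("superpose", reference=ref.label, fitted=len(fitted))

    # pairwise rmsds and receptor-pair grid
    matrix = analysis.pairwise_rmsd_matrix(bundles, method=config.method)
    n_pairs = len(bundles) * (len(bundles) - 1) // 2
    receptor_of = {b.label: b.receptor_id for b in bundles}
    idents = pd.DataFrame(
        [[analysis.sequence_identity(a, b) for b in bundles] for a in bundles],
        index=matrix.index, columns=matrix.columns)
    grid = analysis.average_by_receptor_pair(matrix, receptor_of, identities=idents)
    _stage("pairwise", pairs=n_pairs, groups=grid.n_groups())

    # sections
    if config.section_config is not None:
        sections = SectionDefinition.from_file(config.section_config)
    else:
        sections = section_definition_from_reference(ref)

    # deviation profile in the common frame
    profile = analysis.deviation_profile(fitted)
    _stage("profile", n_pairs=profile.n_pairs)

    # sectional rmsds vs reference
    sect_rows = []
    for b in bundles:
        if b.label == ref.label:
            continue
        vals = analysis.sectional_rmsd(ref, b, sections, method=config.method)
        sect_rows.append([b.label, *np.round(vals, 2)])
    sect_df = pd.DataFrame(sect_rows,
                           columns=["label"] + [f"section{s}" for s in range(1, 6)])
    _stage("sections", chains=len(sect_rows))

    # isolated-helix report
    helix_df = analysis.isolated_helix_comparison(fitted, config.helix_of_interest, ref)
    _stage("isolated_helix", helix=config.helix_of_interest)

    # ionic-lock census
    lock_rows = []
    for b in bundles:
        st = analysis.ionic_lock_state(chains_map[b.label], maps[b.receptor_id],
                                       cutoff=config.ionic_lock_cutoff,
                                       definition=config.definition)
        lock_rows.append(dict(label=b.label, status=st.status,
                              min_distance=(round(st.min_distance, 2)
                                            if st.min_distance is not None else ""),
                              res_3_50=st.residue_350, res_6_30=st.residue_630))
    lock_df = pd.DataFrame(lock_rows)
    n_locked = int((lock_df.status == "locked").sum())
    _stage("ionic_lock", locked=n_locked, total=len(lock_df))

    # write outputs
    write_grid(grid, out / "receptor_pair_grid.tsv")
    write_profile(profile, sections, out / "deviation_profile.tsv",
                  definition=config.definition)
    matrix.round(2).to_csv(out / "pairwise_rmsd.tsv", sep="\t")
    sect_df.to_csv(out / "sectional_rmsd.tsv", sep="\t", index=False)
    helix_df.round(2).to_csv(out / "isolated_helix.tsv", sep="\t")
    lock_df.to_csv(out / "ionic_lock.tsv", sep="\t", index=False)
    pd.DataFrame(excluded).to_csv(out / "excluded_chains.tsv", sep="\t", index=False)

    summary = dict(
        reference=ref.label,
        method=config.method,
        chains_read=int(len(ledger)),
        bundles_extracted=len(bundles),
        excluded=len(excluded),
        n_pairwise_values=n_pairs,
        n_receptor_pair_groups=grid.n_groups(),
        deviation_profile=dict(n_pairs=profile.n_pairs,
                               values=np.round(profile.values, 3).tolist()),
        ionic_lock=dict(locked=n_locked, total=len(lock_df)),
        isolated_helix=dict(helix=config.helix_of_interest,
                            table=helix_df.round(3).to_dict(orient="index")),
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def write_grid(grid: analysis.ReceptorPairGrid, path: str | Path) -> Path:
    """Lower-triangular TSV of "mean (identity)" cells plus a companion sd table.

    Rmsds are printed to 2 decimals, identities to 1; a one-chain receptor
    has no self-pair values, so its diagonal cell stays empty.
    """
    path = Path(path)
    recs = grid.receptors
    lines = ["\t" + "\t".join(recs)]
    for i, r in enumerate(recs):
        cells = []
        for j, s in enumerate(recs):
            if j > i:
                cells.append("")
                continue
            m = grid.mean.loc[r, s]
            if np.isnan(m):
                cells.append("")
                continue
            cell = f"{m:.2f}"
            if grid.identity is not None and not np.isnan(grid.identity.loc[r, s]):
                cell += f" ({grid.identity.loc[r, s]:.1f})"
            cells.append(cell)
        lines.append(r + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    sd_path = path.with_name(path.stem + "_sd" + path.suffix)
    grid.sd.round(3).to_csv(sd_path, sep="\t")
    return path


def write_profile(profile: analysis.DeviationProfile, sections: SectionDefinition,
                  path: str | Path, definition: BundleDefinition = DEFAULT_DEFINITION,
                  plot: bool = False) -> Path:
    """200-row TSV: serial, bw, helix, section, mean deviation, pair count.

    With ``plot`` a figure in the style of a per-position deviation panel is
    written alongside (section-colored points, *.50 tick marks).
    """
    path = Path(path)
    rows = []
    for serial, bw in enumerate(definition.positions()):
        rows.append(dict(serial=serial, bw=str(bw), helix=bw.helix,
                         section=sections.section(bw),
                         mean_dev=round(float(profile.values[serial]), 2),
                         n_pairs=int(profile.counts[serial])))
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    if plot:
        _plot_profile(df, definition, path.with_suffix(".png"))
    return path


def _plot_profile(df: pd.DataFrame, definition: BundleDefinition, png: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {1: "red", 2: "pink", 3: "green", 4: "cyan", 5: "blue"}
    fig, ax = plt.subplots(figsize=(10, 4))
    for s, sub in df.groupby("section"):
        ax.plot(sub.serial, sub.mean_dev, ".", color=colors[s], label=f"section {s}")
    from .numbering import BWNumber, serial_of
    for h in range(1, 8):
        try:
            x = serial_of(BWNumber(h, 50), definition)
            ax.plot([x], [0.02], marker="|", color="black", markersize=10)
        except ValueError:
            pass
    for h in range(1, 7):
        ax.axvline(definition.helix_serial_range(h).stop - 0.5, color="0.8", lw=0.5)
    ax.set_xlabel("serial position in 7TM bundle")
    ax.set_ylabel("averaged deviation (Å)")
    ax.legend(fontsize=7, ncol=5)
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
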