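# Methods

## The problem

Class A G-protein-coupled receptors share a seven-transmembrane (7TM)
helical bundle. Comparing the bundles of different receptors — and of the
same receptor in different states — requires (a) a common residue-level
coordinate system across sequences with < 40 % identity, and (b) a rigid
superposition that separates conserved architecture from receptor-specific
rearrangement. This package implements both, plus the downstream statistics:
pairwise rmsd grids averaged by receptor pair, per-position Cα deviation
profiles, five-slab sectional rmsds, isolated-helix rigid-body comparison,
and an ionic-lock census.

## The 200-residue bundle and BW numbering

The common coordinate system is Ballesteros–Weinstein (BW) numbering: each
helix h carries one maximally conserved anchor residue defined as h.50
(N1.50, D2.50, R3.50, W4.50, P5.50, P6.50, P7.50), and position h.ii counts
relative to it. The analysed bundle is a fixed selection of 200 positions:

| helix | BW range  | length |
|------:|-----------|-------:|
| I     | 1.35–1.59 | 25 |
| II    | 2.38–2.67 | 30 |
| III   | 3.22–3.55 | 34 |
| IV    | 4.39–4.63 | 25 |
| V     | 5.36–5.65 | 30 |
| VI    | 6.29–6.60 | 32 |
| VII   | 7.32–7.55 | 24 |

Because every range is contiguous in BW space, a receptor's mapping to
author (PDB) residue numbers is fully determined by the seven anchor author
numbers (author = anchor + ii − 50). Receptor maps are shipped as plain-text
configs; the bovine rhodopsin map is pinned by well-known landmarks
(Glu113 = 3.28, Arg135 = 3.50, Glu247 = 6.30, Lys296 = 7.43), β2 and A2A use
standard conserved-residue anchors, and the remaining shipped maps are
marked unverified in their `source_note` and should be confirmed against
GPCRDB before production use. Receptors whose structures are known to
disagree locally with sequence alignment (CXCR4 and squid rhodopsin at
helix II, the extracellular side of helix IV) deserve particular caution:
the pure anchor-offset map cannot express a one-residue register shift.
Chains lacking a Cα at any mapped position are rejected with the list of
missing BW positions rather than padded. Insertion codes inside helices are
not supported by the offset map; such chains need an explicit per-position
table.

## Superposition

`kabsch_fit` is the standard least-squares rigid fit (proper rotations
only); the solver is SciPy's `Rotation.align_vectors`, with degenerate
(collinear, N < 3) input rejected. `ssm_fit` is a two-stage
secondary-structure-matching style fit for bundles:

1. each of the seven helices is reduced to three pseudo-points (centroid
   and centroid ± quarter length along the N→C principal axis, the axis
   being the first principal component of the helix Cαs), and a Kabsch fit
   over the 21 matched pseudo-points gives the initial transform;
2. iterated trimmed least squares on the 200 Cα pairs: each round, pairs
   farther than min(cutoff, max(0.5 Å, 2 × rms of the currently matched
   pairs)) are discarded and the fit recomputed, until the matched set is
   stable (max 20 rounds; non-convergence returns the best fit with a
   warning flag).

The hard cutoff defaults to 3.0 Å; both constants are configurable. The
adaptive 2×rms term makes the refinement lock onto the mutually consistent
core when one helix is rigidly displaced by less than the hard cutoff —
with a fixed threshold a 2 Å single-helix displacement would be partially
absorbed into the global fit instead of appearing in the deviation profile.
The 0.5 Å floor prevents the threshold from collapsing to zero on a
noise-free matched core. The reported rmsd always covers all 200 positions
in the converged frame; `n_matched` records the trimmed count separately,
which keeps rmsd values comparable between methods and across pairs.

Deviation profiles average the per-position Cα–Cα distances over all chain
pairs after every bundle is fitted once onto a single common reference
chain (default: the β2 receptor chain when present). Fresh per-pair fitting
is available via `frame="pairwise"`. On synthetic ensembles the profile
changes by well under 0.3 Å per position when the reference is swapped,
matching the expectation that the choice of reference is immaterial.

## Membrane sections

The bundle is divided into five slabs stacked along the membrane normal,
section 1 at the extracellular surface (ligand entry path) and section 5 at
the cytoplasmic surface (D/ERY motif, G-protein side). The default
partition is constructed geometrically from a reference bundle: helix IV is
taken as perpendicular to the membrane plane, its 25 bundle residues are cut
into five consecutive 5-residue blocks, and every position joins the section
whose helix IV block is nearest along the helix IV axis. Each slab comes out
roughly 7.5 Å thick. A user-supplied per-position table overrides the
construction. Sectional rmsds are computed in the whole-bundle fitted frame
without refitting, so the position-count-weighted mean of squared sectional
rmsds equals the squared all-200 rmsd exactly — a useful internal check.

## Isolated-helix comparison

A helix that is rigidly displaced within the bundle but internally
unchanged shows a characteristic contrast: large in-bundle deviation, small
isolated-fit rmsd. Three numbers are reported per chain: the mean Cα
deviation of the helix in the common frame; the norm of the mean deviation
vector after re-expressing the chain in a frame fitted on the other six
helices only (`net_displacement` — excluding the helix under scrutiny from
the frame fit keeps small displacements from being diluted, and averaging
the vector before taking the norm suppresses noise by √n); and the rmsd of
the helix fitted in isolation onto the reference helix. On synthetic
bundles with a single-helix translation of 0.5–4 Å under 0.2 Å coordinate
noise, `net_displacement` recovers the injected value within 0.15 Å.

## Secondary structure and kinks

Crystal structures lack hydrogens, so backbone amide hydrogens are placed
1.0 Å from N opposing the preceding carbonyl
(H = N + normalize(normalize(N−C') + normalize(C'−O'))); chain starts and
prolines get none. Hydrogen bonds use the classic Kabsch–Sander
electrostatic energy E = 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)
kcal/mol, bonded below −0.5, clashes (< 0.5 Å) capped at −9.9. Two
consecutive i→i+4 turns assign α-helix (H); the analogous i→i+3 / i→i+5
patterns give 3₁₀ (G) and π (I), leftover single turns T. Sheet ladders and
solvent accessibility are out of scope. Helix regularity is quantified by a
windowed kink angle: at each interior position, the angle between the
principal axes of the preceding and following 8-residue windows (window 7).
"No obvious kink" is operationalised as max kink angle < 15° — a documented
default, not an external standard.

## Ionic lock

The lock is scored on the original chain (with side chains), not the Cα
bundle: locked iff the residue at 6.30 is Glu or Asp and the minimal
distance from the Arg 3.50 guanidinium nitrogens (NE, NH1, NH2) to the
carboxylate oxygens (OE1/OE2 or OD1/OD2) is at most 4.0 Å — the
conventional salt-bridge threshold, configurable. A non-acidic 6.30 gives
`no_acidic_partner`; unresolved side chains give `indeterminate`; a non-Arg
3.50 is reported unlocked with a warning.

## Chain classification and screening

State is a pure function of the bound-ligand class: antagonist or inverse
agonist ⇒ inactivated; agonist or ligand-free ⇒ activated. Unknown classes
are an error, never a default. The outlier screen flags chains of one
receptor whose mean Cα deviation from the group's medoid chain (after a
whole-bundle fit) exceeds a threshold (default 2.0 Å) inside a stated BW
region; with a majority of mutually similar outliers a medoid-based screen
would invert, so it is intended for the realistic case of individually
deviant chains.

Receptor-pair grids use arithmetic means of the chain-pair rmsds (not
pooled squares); pair counts obey n_r·n_s for distinct receptors and
n_r(n_r−1)/2 within a receptor, self-pairs existing only for receptors with
at least two chains. Sequence identity is computed over the 200 aligned
bundle positions, not the full sequences. Display rounding follows the
field's tables: rmsd to 2 decimals, identity to 1.

## The synthetic generator

Synthetic bundles exist so that every stage is testable without downloads:
seven ideal α-helices (rise 1.5 Å/residue, twist 100°/residue, Cα radius
2.3 Å — canonical values, configurable) with centroids on a 12 Å circle,
antiparallel alternation oriented so that helix IV's N-terminus (4.39) lies
cytoplasmic as in real receptors. Backbone N/C/O atoms sit on co-axial
helical curves whose cylindrical offsets were frozen from ideal φ=−57°,
ψ=−47° internal geometry, so the hydrogen-bond-based assignment labels the
helices H. Perturbations are rigid-body (whole-helix translation/rotation)
plus seeded isotropic Gaussian noise per atom — no B-factor correlation
structure, no side chains beyond explicitly placed pseudo-atoms for
ionic-lock tests (labelled synthetic by construction), no receptor-specific
packing, no loops connecting the helices. Passing tests on these ensembles
therefore demonstrate the correctness of the geometry and statistics, not
robustness to real crystallographic pathologies (alternate conformations in
loops, fusion-partner distortions, register shifts).

## Problem sizes and determinism

The shipped test-suite and acceptance-script runs use a 50-chain census
with per-receptor chain counts (11, 5, 5, 12, 6, 5, 2, 1, 1, 2), a 9-chain
ensemble (36 pairs) for profiles, and a 10-chain ionic-lock census — the
same shapes as the published crystallographic census, generated rather than
downloaded. All randomness flows from explicit seeds; reruns with the same
config are byte-identical. Statistics on the real PDB entries are supported
through the same code path (`tmbundle fetch` + `tmbundle analyze`) when the
entries are available locally.

## Known limitations

- Anchor maps for eight of the eleven shipped receptors are unverified
  (see their `source_note`); the bundle extraction is only as good as the
  anchors.
- The anchor-offset map cannot represent insertion codes or register
  shifts within a helix.
- SSM here matches helices by bundle position (helix k to helix k), not by
  searching over element correspondences; it is not a general structure
  aligner.
- Only model 1 of multi-model files is used; altloc resolution is by
  occupancy (tie → "A", then blank).
- The five-section partition is a geometric reconstruction from a reference
  bundle, not a transcription of any published per-position table; users
  can supply their own table.
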