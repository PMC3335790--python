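"""Classification, pair grids, profiles, sections, helix comparison, ionic lock."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tmbundle.analysis import (average_by_receptor_pair, classify_chain,
                               deviation_profile, fit_all_to_reference,
                               ionic_lock_state, isolated_helix_comparison,
                               outlier_screen, pairwise_rmsd_matrix,
                               sectional_rmsd, sequence_identity)
from tmbundle.numbering import BWNumber, extract_bundle, section_definition_from_reference
from tmbundle.synthetic import add_ionic_lock_sidechains, build_bundle

from conftest import bundle_with


@pytest.mark.parametrize("ligand, state", [
    ("antagonist", "inactivated"),
    ("inverse_agonist", "inactivated"),
    ("inverse-agonist", "inactivated"),
    ("agonist", "activated"),
    ("ligand_free", "activated"),
])
def test_classify_chain_ligand_rule(ligand, state):
    assert classify_chain(ligand) == state


def test_classify_chain_rejects_unknown_class():
    with pytest.raises(ValueError, match="allosteric"):
        classify_chain("allosteric")


class TestPairwiseMatrix:
    def test_unique_value_counts_match_combinatorics(self, clean_chain):
        chain, rmap = clean_chain
        bundles = [bundle_with(chain, rmap, entry_id=f"S{i}", sigma=0.05, seed=i)
                   for i in range(5)]
        m = pairwise_rmsd_matrix(bundles, method="kabsch")
        assert np.allclose(np.diag(m.values), 0)
        assert np.allclose(m.values, m.values.T)
        iu = np.triu_indices(5, k=1)
        assert len(m.values[iu]) == 5 * 4 // 2

    def test_identical_bundles_give_zero(self, clean_bundle):
        twin = bundle_with(*build_bundle(), entry_id="TWIN")
        m = pairwise_rmsd_matrix([clean_bundle, twin])
        assert m.values[0, 1] < 1e-9

    def test_single_bundle_rejected(self, clean_bundle):
        with pytest.raises(ValueError):
            pairwise_rmsd_matrix([clean_bundle])


class TestReceptorPairGrid:
    def make_matrix(self, counts):
        """Chain-level matrix with the given per-receptor chain counts."""
        labels, receptor_of = [], {}
        for r, n in enumerate(counts):
            for c in range(n):
                lab = f"R{r}C{c}"
                labels.append(lab)
                receptor_of[lab] = f"R{r}"
        rng = np.random.default_rng(0)
        n = len(labels)
        vals = rng.uniform(0.5, 3.0, size=(n, n))
        m = np.triu(vals, 1)
        m = m + m.T
        return pd.DataFrame(m, index=labels, columns=labels), receptor_of

    def test_group_count_for_the_published_chain_census(self):
        # 43 chains over 10 receptors -> 45 cross pairs + 8 self pairs = 53
        counts = (11, 5, 5, 5, 6, 5, 2, 1, 1, 2)
        matrix, receptor_of = self.make_matrix(counts)
        grid = average_by_receptor_pair(matrix, receptor_of)
        assert grid.n_groups() == 53
        total = sum(int(grid.n_values.loc[r, s])
                    for i, r in enumerate(grid.receptors)
                    for s in grid.receptors[i:])
        assert total == 43 * 42 // 2 == 903

    def test_self_pair_count_closed_form(self):
        matrix, receptor_of = self.make_matrix((11, 2))
        grid = average_by_receptor_pair(matrix, receptor_of)
        assert grid.n_values.loc["R0", "R0"] == 11 * 10 // 2 == 55
        assert grid.n_values.loc["R0", "R1"] == 11 * 2

    def test_single_chain_receptor_has_no_self_pair(self):
        matrix, receptor_of = self.make_matrix((3, 1))
        grid = average_by_receptor_pair(matrix, receptor_of)
        assert np.isnan(grid.mean.loc["R1", "R1"])

    def test_identical_chains_mean_and_sd_zero(self, clean_chain):
        chain, rmap = clean_chain
        bundles = [bundle_with(chain, rmap, entry_id=f"S{i}") for i in range(3)]
        m = pairwise_rmsd_matrix(bundles, method="kabsch")
        grid = average_by_receptor_pair(m, {b.label: "syn" for b in bundles})
        assert grid.mean.loc["syn", "syn"] == pytest.approx(0.0, abs=1e-9)
        assert grid.sd.loc["syn", "syn"] == pytest.approx(0.0, abs=1e-9)

    def test_unlabeled_chain_rejected(self):
        matrix, receptor_of = self.make_matrix((2, 2))
        del receptor_of["R1C1"]
        with pytest.raises(ValueError, match="unlabeled"):
            average_by_receptor_pair(matrix, receptor_of)


class TestDeviationProfile:
    def test_duplicates_give_all_zero(self, clean_chain):
        chain, rmap = clean_chain
        bundles = [bundle_with(chain, rmap, entry_id=f"S{i}") for i in range(3)]
        prof = deviation_profile(bundles)
        assert prof.values.max() < 1e-9
        assert prof.n_pairs == 3

    def test_pair_count_with_nine_chains(self, clean_chain):
        chain, rmap = clean_chain
        bundles = [bundle_with(chain, rmap, entry_id=f"S{i}", sigma=0.05, seed=i)
                   for i in range(9)]
        ref = bundles[0]
        prof = deviation_profile(fit_all_to_reference(bundles, ref))
        assert prof.n_pairs == 36

    def test_shifted_helix_elevates_only_its_serials(self, clean_chain, clean_bundle):
        chain, rmap = clean_chain
        bundles = [clean_bundle,
                   bundle_with(chain, rmap, entry_id="SH", helix=3,
                               translation=(2.0, 0, 0)),
                   bundle_with(chain, rmap, entry_id="S2")]
        prof = deviation_profile(fit_all_to_reference(bundles, clean_bundle))
        r3 = clean_bundle.definition.helix_serial_range(3)
        inside = prof.values[r3.start:r3.stop]
        outside = np.delete(prof.values, range(r3.start, r3.stop))
        assert inside.mean() > 1.0
        assert outside.max() < 0.1

    def test_single_bundle_rejected(self, clean_bundle):
        with pytest.raises(ValueError):
            deviation_profile([clean_bundle])


class TestSectionalRmsd:
    def test_identical_bundles_five_zeros(self, clean_bundle):
        sections = section_definition_from_reference(clean_bundle)
        vals = sectional_rmsd(clean_bundle, clean_bundle, sections)
        assert np.allclose(vals, 0, atol=1e-9)
        assert len(vals) == 5

    def test_weighted_square_identity_with_total(self, clean_chain, clean_bundle):
        from tmbundle.superpose import ssm_fit
        chain, rmap = clean_chain
        other = bundle_with(chain, rmap, helix=2, translation=(1.2, 0, 0),
                            sigma=0.15, seed=4)
        sections = section_definition_from_reference(clean_bundle)
        vals = sectional_rmsd(clean_bundle, other, sections)
        total = ssm_fit(other, clean_bundle).rmsd
        counts = np.array([
            sum(1 for bw in clean_bundle.bw if sections.section(bw) == s)
            for s in range(1, 6)])
        assert counts.sum() == 200
        assert np.sqrt((counts * vals ** 2).sum() / 200) == pytest.approx(total, abs=1e-9)

    def test_perturbation_localized_to_one_section(self, clean_chain, clean_bundle):
        # expand section 1 radially (outward from the bundle axis) — a
        # deformation no rigid motion can absorb — and leave the rest alone
        sections = section_definition_from_reference(clean_bundle)
        target = {bw for bw in clean_bundle.bw if sections.section(bw) == 1}
        chain, rmap = clean_chain
        from tmbundle.numbering import author_to_bw
        from tmbundle.structure_io import AtomRecord, ChainModel
        center = clean_bundle.coords.mean(axis=0)
        new_residues = []
        for key, atoms in chain.residues:
            bw = author_to_bw(rmap, key.author_seq_number)
            shift = np.zeros(3)
            if bw in target:
                ca = next(a.coord for a in atoms if a.name == "CA")
                radial = np.array([ca[0] - center[0], ca[1] - center[1], 0.0])
                shift = 1.5 * radial / np.linalg.norm(radial)
            new_residues.append((key, [AtomRecord(a.name, a.element, a.coord + shift,
                                                  a.occupancy, a.altloc)
                                       for a in atoms]))
        moved = ChainModel("SEC1", "A", 1, new_residues)
        other = extract_bundle(moved, rmap)
        vals = sectional_rmsd(clean_bundle, other, sections)
        assert vals[0] == max(vals)
        assert vals[0] > 3 * max(vals[1:])


class TestIsolatedHelix:
    def test_rigid_shift_signature(self, clean_chain, clean_bundle):
        chain, rmap = clean_chain
        moved = bundle_with(chain, rmap, entry_id="MV", helix=3,
                            translation=(2.0, 0, 0))
        fitted = fit_all_to_reference([clean_bundle, moved], clean_bundle)
        df = isolated_helix_comparison(fitted, 3, clean_bundle)
        row = df.loc["MV-A"]
        assert row.bundle_frame_deviation == pytest.approx(2.0, abs=0.1)
        assert row.net_displacement == pytest.approx(2.0, abs=0.05)
        assert row.isolated_rmsd < 1e-9

    def test_unperturbed_chain_near_zero(self, clean_chain, clean_bundle):
        chain, rmap = clean_chain
        twin = bundle_with(chain, rmap, entry_id="TW")
        fitted = fit_all_to_reference([clean_bundle, twin], clean_bundle)
        df = isolated_helix_comparison(fitted, 3, clean_bundle)
        row = df.loc["TW-A"]
        assert row.bundle_frame_deviation < 1e-9
        assert row.isolated_rmsd < 1e-9

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0, 4.0])
    def test_parameter_recovery_under_noise(self, clean_chain, clean_bundle, d):
        chain, rmap = clean_chain
        moved = bundle_with(chain, rmap, entry_id="MV", helix=3,
                            translation=(d, 0, 0), sigma=0.2, seed=int(d * 10))
        fitted = fit_all_to_reference([clean_bundle, moved], clean_bundle)
        df = isolated_helix_comparison(fitted, 3, clean_bundle)
        assert df.loc["MV-A"].net_displacement == pytest.approx(d, abs=0.15)


class TestIonicLock:
    def make_chain(self, distance, acidic="GLU"):
        chain, rmap = build_bundle()
        add_ionic_lock_sidechains(chain, rmap, distance=distance, acidic=acidic)
        return chain, rmap

    def test_close_salt_bridge_locked(self):
        chain, rmap = self.make_chain(3.0)
        st = ionic_lock_state(chain, rmap)
        assert st.status == "locked"
        assert st.min_distance == pytest.approx(3.0, abs=0.05)

    def test_distant_pair_unlocked(self):
        chain, rmap = self.make_chain(6.5)
        st = ionic_lock_state(chain, rmap)
        assert st.status == "unlocked"
        assert st.min_distance > 4.0

    def test_cutoff_is_configurable(self):
        chain, rmap = self.make_chain(4.5)
        assert ionic_lock_state(chain, rmap, cutoff=4.0).status == "unlocked"
        assert ionic_lock_state(chain, rmap, cutoff=5.0).status == "locked"

    def test_aspartate_partner_counts(self):
        chain, rmap = self.make_chain(3.2, acidic="ASP")
        assert ionic_lock_state(chain, rmap).status == "locked"

    def test_non_acidic_partner(self):
        chain, rmap = self.make_chain(3.0, acidic="ALA")
        assert ionic_lock_state(chain, rmap).status == "no_acidic_partner"

    def test_plain_synthetic_chain_indeterminate_without_sidechains(self):
        chain, rmap = build_bundle()
        # rename 3.50/6.30 appropriately but give no side-chain atoms
        add_ionic_lock_sidechains(chain, rmap, distance=3.0)
        from tmbundle.numbering import BWNumber, bw_to_author
        num = bw_to_author(rmap, BWNumber(3, 50))
        for i, (key, atoms) in enumerate(chain.residues):
            if key.author_seq_number == num:
                chain.residues[i] = (key, [a for a in atoms
                                           if a.name in ("N", "CA", "C", "O")])
        assert ionic_lock_state(chain, rmap).status == "indeterminate"

    def test_non_arginine_reported_unlocked_with_warning(self, caplog):
        chain, rmap = build_bundle()  # all-ALA sequence: 3.50 is not Arg
        with caplog.at_level("WARNING"):
            st = ionic_lock_state(chain, rmap)
        assert st.status == "unlocked"
        assert any("not Arg" in r.message for r in caplog.records)


class TestSequenceIdentity:
    def test_self_is_100(self, clean_bundle):
        assert sequence_identity(clean_bundle, clean_bundle) == 100.0

    @pytest.mark.parametrize("n_diff, expected", [(50, 75.0), (75, 62.5)])
    def test_mismatch_arithmetic(self, clean_chain, n_diff, expected):
        chain, rmap = clean_chain
        seq = list("A" * 200)
        for i in range(n_diff):
            seq[i] = "G"
        other_chain, other_map = build_bundle(sequence="".join(seq), entry_id="SEQ2")
        a = extract_bundle(chain, rmap)
        b = extract_bundle(other_chain, other_map)
        assert sequence_identity(a, b) == expected
        assert sequence_identity(b, a) == expected


class TestOutlierScreen:
    region = (BWNumber(1, 35), BWNumber(1, 44))

    def test_displaced_n_terminus_flagged(self, clean_chain):
        chain, rmap = clean_chain
        bundles = [bundle_with(chain, rmap, entry_id=f"S{i}", sigma=0.05, seed=i)
                   for i in range(3)]
        bad = bundle_with(chain, rmap, entry_id="BAD", helix=1,
                          translation=(3.0, 0, 0), sigma=0.05, seed=99)
        flagged = outlier_screen(bundles + [bad], self.region, threshold=2.0)
        assert flagged == ["BAD-A"]

    def test_homogeneous_set_clean(self, clean_chain):
        chain, rmap = clean_chain
        bundles = [bundle_with(chain, rmap, entry_id=f"S{i}", sigma=0.05, seed=i)
                   for i in range(4)]
        assert outlier_screen(bundles, self.region, threshold=2.0) == []

    def test_zero_threshold_flags_all_non_medoid(self, clean_chain):
        chain, rmap = clean_chain
        bundles = [bundle_with(chain, rmap, entry_id=f"S{i}", sigma=0.05, seed=i)
                   for i in range(4)]
        flagged = outlier_screen(bundles, self.region, threshold=0.0)
        assert len(flagged) == 3
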