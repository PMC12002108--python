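import numpy as np
import pytest

from zndesign.fixtures import (
    SCENE_KINDS,
    build_anchor_pair_chain,
    build_design_scene,
    build_ideal_helix,
    generate_itc_data,
    oracle_mine,
    write_fixture_set,
)
from zndesign.mining import mine_fragments, build_library
from zndesign.assembly import enumerate_designs
from zndesign.secstruct import assign_ss, phi_psi, terminal_helix_filter
from zndesign.structure import read_structure, write_structure, one_letter_sequence


class TestIdealHelix:
    def test_rise_per_residue(self):
        st = build_ideal_helix("A" * 12)
        ca = np.array([r.atom("CA").coords for r in st.chains[0]])
        centered = ca - ca.mean(axis=0)
        axis = np.linalg.svd(centered)[2][0]
        rise = abs(np.polyfit(range(len(ca)), centered @ axis, 1)[0])
        assert rise == pytest.approx(1.5, abs=0.1)

    def test_requested_dihedrals_realized(self):
        st = build_ideal_helix("A" * 8, phi=-63.0, psi=-42.0)
        for phi, psi in phi_psi(st.chains[0].residues)[1:-1]:
            assert phi == pytest.approx(-63.0, abs=1.0)
            assert psi == pytest.approx(-42.0, abs=1.0)

    def test_extended_chain_end_to_end(self):
        n = 10
        st = build_ideal_helix("A" * n, phi=180.0, psi=180.0)
        ca = [r.atom("CA").coords for r in st.chains[0]]
        assert np.linalg.norm(ca[-1] - ca[0]) > 3.0 * (n - 1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_ideal_helix("")

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            build_ideal_helix("AZ")

    def test_peptide_bonds_continuous(self):
        st = build_ideal_helix("HAC" * 5)
        res = st.chains[0].residues
        for a, b in zip(res, res[1:]):
            d = np.linalg.norm(a.atom("C").coords - b.atom("N").coords)
            assert d == pytest.approx(1.329, abs=1e-6)


class TestScenes:
    def test_positive_scene_admits_design(self, positive_scene):
        designs = enumerate_designs(build_library([positive_scene]))
        assert len(designs) >= 1
        assert terminal_helix_filter(assign_ss(designs[0]))

    def test_donor_far_scene_kills_cross_fragments(self, negative_scenes):
        st = negative_scenes["donor_far"]
        frags = mine_fragments(st)
        assert all(f.anchor_start.seq_number != 1 for f in frags)
        assert enumerate_designs(build_library([st])) == []

    def test_long_gap_scene_has_no_fragments(self, negative_scenes):
        assert mine_fragments(negative_scenes["long_gap"]) == []

    def test_wrong_composition_scene_filtered(self, negative_scenes):
        st = negative_scenes["wrong_composition"]
        assert len(mine_fragments(st)) > 0  # mining is fine; the site screen rejects
        assert enumerate_designs(build_library([st])) == []

    def test_terminal_coil_scene_fails_ss_screen(self, negative_scenes):
        st = negative_scenes["terminal_coil"]
        designs = enumerate_designs(build_library([st]))
        assert len(designs) >= 1  # geometry is fine
        assert not terminal_helix_filter(assign_ss(designs[0]))

    @pytest.mark.parametrize("seed", range(20))
    def test_constructed_outcomes_hold_across_seeds(self, seed):
        pos = build_design_scene("positive", seed=seed)
        assert len(enumerate_designs(build_library([pos]))) >= 1
        neg = build_design_scene("wrong_composition", seed=seed)
        assert enumerate_designs(build_library([neg])) == []

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_design_scene("bogus")

    @pytest.mark.parametrize("kind", SCENE_KINDS)
    def test_scenes_round_trip_through_pdb(self, kind, positive_scene, negative_scenes):
        st = positive_scene if kind == "positive" else negative_scenes[kind]
        back = read_structure(write_structure(st), source_id=st.source_id)
        assert one_letter_sequence(back.chains[0]) == one_letter_sequence(st.chains[0])
        assert {f.key for f in mine_fragments(back)} == oracle_mine(back)
        # outcome survives coordinate quantization to PDB precision
        assert oracle_mine(back) == oracle_mine(st)


class TestAnchorPairChain:
    @pytest.mark.parametrize("distance", [1.5, 4.0, 6.5, 7.2])
    def test_exact_engineered_donor_distance(self, distance):
        st = build_anchor_pair_chain(n_interior=5, donor_distance=distance)
        his, cys = st.chains[0].residues[0], st.chains[0].residues[-1]
        nd1 = his.atom("ND1").coords
        ne2 = his.atom("NE2").coords
        sg = cys.atom("SG").coords
        assert np.linalg.norm(sg - nd1) == pytest.approx(distance, abs=1e-9)
        assert np.linalg.norm(sg - ne2) > distance


class TestItcGenerator:
    def test_zero_noise_is_exactly_linear(self):
        data = generate_itc_data(dH_bind=-2.0, n_Hplus=-1.5, sigma=0.0, seed=0)
        for t in data:
            assert t.dH_obs == pytest.approx(-2.0 + (-1.5) * t.dH_ion, abs=1e-12)

    def test_seed_reproducibility(self):
        a = generate_itc_data(-2.9, -1.8, sigma=0.1, seed=42)
        b = generate_itc_data(-2.9, -1.8, sigma=0.1, seed=42)
        assert [t.dH_obs for t in a] == [t.dH_obs for t in b]

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            generate_itc_data(-2.9, -1.8, sigma=-0.1, seed=0)


class TestFixtureSet:
    def test_manifest_and_files(self, tmp_path):
        manifest = write_fixture_set(tmp_path, seed=5)
        assert len(manifest["structures"]) == len(SCENE_KINDS) + 1
        for entry in manifest["structures"]:
            assert (tmp_path / entry["file"]).exists()
        assert (tmp_path / manifest["itc"]).exists()
        assert (tmp_path / "manifest.json").exists()
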