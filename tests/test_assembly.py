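import numpy as np
import pytest

from zndesign.assembly import (
    MergeRejected,
    SharedFragmentMismatchError,
    as_peptide,
    assemble_candidates,
    enumerate_designs,
    find_compatible,
    merge_final,
    merge_pair,
)
from zndesign.fixtures import build_random_hc_scene, oracle_knn, oracle_mine
from zndesign.mining import build_library, fragment_from_chain
from zndesign.superpose import RigidTransform


@pytest.fixture(scope="module")
def p1_fragments(p1_model):
    """The three fragments whose merge reconstructs the P1 design."""
    return (
        fragment_from_chain(p1_model, "A", 0, 4),    # H1..C5
        fragment_from_chain(p1_model, "A", 4, 17),   # C5..H18
        fragment_from_chain(p1_model, "A", 17, 21),  # H18..C22
    )


class TestFindCompatible:
    def test_identical_terminal_context_ranks_first(self, positive_scene):
        lib = build_library([positive_scene])
        query = lib[0]
        ranked = find_compatible(query, lib, k=10)
        assert ranked, "expected at least one compatible fragment"
        top_frag, top_score = ranked[0]
        assert top_score.rmsd < 1e-9
        assert top_frag.anchor_start.seq_number == query.anchor_end.seq_number

    def test_compatibility_letter_filter(self, p1_fragments):
        from zndesign.mining import FragmentLibrary

        f1, f2, f3 = p1_fragments
        # f1 ends in Cys: a library whose only fragment starts with His is useless
        assert find_compatible(f1, FragmentLibrary(fragments=[f3]), k=5) == []
        # while the Cys-start fragment matches
        assert len(find_compatible(f1, FragmentLibrary(fragments=[f2]), k=5)) == 1

    def test_empty_library(self, p1_fragments):
        from zndesign.mining import FragmentLibrary

        assert find_compatible(p1_fragments[0], FragmentLibrary(), k=10) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_topk_matches_exhaustive_oracle(self, seed):
        st = build_random_hc_scene(seed)
        lib = build_library([st])
        if len(lib) == 0:
            assert oracle_mine(st) == set()
            return
        query = lib[0]
        ours = find_compatible(query, lib, k=5)
        ref = oracle_knn(query, lib, k=5)
        assert len(ours) == len(ref)
        np.testing.assert_allclose(
            [s.rmsd for _, s in ours], [r for _, r in ref], atol=1e-8
        )
        # set equality of keys modulo ties: compare sorted (rmsd, key) lists
        ours_keys = sorted((round(s.rmsd, 6), f.key) for f, s in ours)
        ref_keys = sorted((round(r, 6), k) for k, r in ref)
        assert ours_keys == ref_keys


class TestMergePair:
    def test_p1_first_merge(self, p1_fragments):
        f1, f2, _ = p1_fragments
        merged = merge_pair(f1, f2)
        assert merged.sequence == "HMENCERRFARSDELSRH"
        assert merged.anchor_positions == (1, 5, 18)
        assert len(merged.residues) == len(f1.residues) + len(f2.residues) - 1

    def test_first_component_coordinates_untouched(self, p1_fragments):
        f1, f2, _ = p1_fragments
        merged = merge_pair(f1, f2)
        for res, orig in zip(merged.residues[:5], f1.residues):
            for atom in orig.atoms:
                np.testing.assert_array_equal(res.atom(atom.name).coords, atom.coords)

    def test_translated_copy_merges_exactly(self, p1_fragments):
        import copy

        f1, f2, _ = p1_fragments
        shifted = copy.deepcopy(f2)
        t = RigidTransform(np.eye(3), np.array([10.0, -4.0, 2.0]))
        for res in shifted.residues:
            for atom in res.atoms:
                atom.coords = t.apply(atom.coords)
        merged = merge_pair(f1, shifted)
        assert merged.sequence == "HMENCERRFARSDELSRH"
        # the moved copy aligns back onto the original frame
        for res, orig in zip(merged.residues[5:], f2.residues[1:]):
            for atom in orig.atoms:
                np.testing.assert_allclose(res.atom(atom.name).coords, atom.coords, atol=1e-8)

    def test_incompatible_anchors_error(self, p1_fragments):
        f1, _, f3 = p1_fragments
        with pytest.raises(Exception):
            merge_pair(f1, f3)  # C5 end vs H18 start

    def test_rmsd_ceiling_rejects(self, p1_fragments):
        import copy

        f1, f2, _ = p1_fragments
        bent = copy.deepcopy(f2)
        bent.residues[0].atom("SG").coords = bent.residues[0].atom("SG").coords + 3.0
        with pytest.raises(MergeRejected):
            merge_pair(f1, bent, max_rmsd=0.5)


class TestMergeFinal:
    def test_p1_reconstruction(self, p1_fragments):
        f1, f2, f3 = p1_fragments
        left = merge_pair(f1, f2)
        right = merge_pair(f2, f3)
        final = merge_final(left, right)
        assert final.sequence == "HMENCERRFARSDELSRHAHKC"
        assert final.anchor_positions == (1, 5, 18, 22)
        assert final.stage == "4-anchor"
        assert final.merge_rmsds[-1] < 1e-9

    def test_length_arithmetic(self, p1_fragments):
        f1, f2, f3 = p1_fragments
        left, right = merge_pair(f1, f2), merge_pair(f2, f3)
        final = merge_final(left, right)
        overlap = len(f2.residues)
        assert len(final.residues) == len(left.residues) + len(right.residues) - overlap

    def test_provenance_reconstructs_sequence(self, p1_fragments):
        f1, f2, f3 = p1_fragments
        final = merge_final(merge_pair(f1, f2), merge_pair(f2, f3))
        rebuilt = f1.sequence + f2.sequence[1:] + f3.sequence[1:]
        assert rebuilt == final.sequence
        assert [f.key for f in final.provenance] == [f1.key, f2.key, f3.key]

    def test_shared_sequence_mismatch_error(self, p1_fragments, p1_model):
        f1, f2, f3 = p1_fragments
        left = merge_pair(f1, f2)
        other = fragment_from_chain(p1_model, "A", 17, 21)
        right = merge_pair(f2, other)
        # corrupt one shared-position letter on the right copy
        right.residues[3].aa_code = "A"
        with pytest.raises(SharedFragmentMismatchError):
            merge_final(left, right)


class TestEnumerateDesigns:
    def test_positive_scene_admits_exactly_one_design(self, positive_scene):
        lib = build_library([positive_scene])
        designs = enumerate_designs(lib)
        assert len(designs) == 1
        (d,) = designs
        assert d.anchor_positions == (1, 5, 16, 20)
        assert d.anchor_composition == "CCHH"

    def test_empty_library_yields_nothing(self):
        from zndesign.mining import FragmentLibrary

        assert enumerate_designs(FragmentLibrary()) == []

    def test_k1_subset_of_k10(self, positive_scene):
        lib = build_library([positive_scene])
        small = {d.sequence for d in enumerate_designs(lib, k=1)}
        large = {d.sequence for d in enumerate_designs(lib, k=10)}
        assert small <= large

    def test_candidates_satisfy_invariants(self, positive_scene):
        lib = build_library([positive_scene])
        for pep in assemble_candidates(lib):
            assert pep.n_anchors == 4
            assert pep.anchor_positions[0] == 1
            assert pep.anchor_positions[-1] == len(pep.residues)
            assert all(r.aa_code in "HC" for r in pep.anchor_residues)


class TestAsPeptide:
    def test_fragment_view(self, p1_fragments):
        pep = as_peptide(p1_fragments[0])
        assert pep.anchor_positions == (1, 5)
        assert pep.stage == "fragment"
        assert pep.sequence == "HMENC"
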