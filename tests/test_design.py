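"""Tiling, substitutions, construct assembly, and epitope refinement."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minigene import (
    FragmentSpec,
    ProteinRecord,
    RefinementNode,
    SubstitutionSpec,
    apply_substitutions,
    assemble_construct,
    epitope_interval,
    fragment_from_interval,
    random_protein,
    refine_fragment,
    tile_protein,
)
from minigene.design import n_tiles, tile_intervals
from minigene.errors import (
    InconsistentEpitopes,
    InvalidConfigError,
    InvalidInputError,
    NoPositiveFragments,
    ProvenanceError,
    RefinementExhausted,
)


def covered_residues(fragments):
    cov = set()
    for f in fragments:
        cov.update(range(f.start, f.end + 1))
    return cov


class TestTiling:
    @pytest.mark.parametrize(
        "length,window,overlap,expected_n",
        [
            (1315, 400, 30, 4),  # full tetanospasmin length
            (400, 400, 30, 1),   # fits one window
            (430, 400, 30, 2),
            (1, 5, 1, 1),
            (801, 400, 30, 3),
        ],
    )
    def test_fragment_count_and_coverage(self, length, window, overlap, expected_n):
        p = random_protein(length, seed=1)
        frags = tile_protein(p, window, overlap)
        assert len(frags) == expected_n
        assert covered_residues(frags) == set(range(1, length + 1))
        assert frags[0].start == 1 and frags[-1].end == length

    def test_single_window_protein_is_one_fragment(self):
        p = random_protein(400, seed=2)
        (frag,) = tile_protein(p, 400, 30)
        assert (frag.start, frag.end) == (1, 400)
        assert frag.sequence == p.sequence

    def test_two_fragment_layout_overlap(self):
        p = random_protein(430, seed=3)
        a, b = tile_protein(p, 400, 30)
        overlap = a.end - b.start + 1
        assert overlap >= 30
        assert (a.start, b.end) == (1, 430)

    def test_invalid_configs(self):
        p = random_protein(100, seed=4)
        with pytest.raises(InvalidConfigError):
            tile_protein(p, window=30, min_overlap=30)
        with pytest.raises(InvalidConfigError):
            tile_protein(p, window=10, min_overlap=20)
        with pytest.raises(InvalidInputError):
            tile_intervals(0, 400, 30)
        with pytest.raises(InvalidInputError):
            ProteinRecord("empty", "")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        length=st.integers(1, 5000),
        window=st.integers(2, 500),
        overlap_frac=st.floats(0.01, 0.99),
    )
    def test_tiling_invariants(self, length, window, overlap_frac):
        """Coverage, overlap, and the closed-form minimum fragment count."""
        overlap = max(1, min(window - 1, int(window * overlap_frac)))
        intervals = tile_intervals(length, window, overlap)
        assert intervals[0][0] == 1 and intervals[-1][1] == length
        covered = set()
        for s, e in intervals:
            assert 1 <= s <= e <= length
            assert e - s + 1 <= window
            covered.update(range(s, e + 1))
        assert covered == set(range(1, length + 1))
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert s2 > s1
            assert e1 - s2 + 1 >= overlap
        expected = 1 if length <= window else math.ceil((length - window) / (window - overlap)) + 1
        assert len(intervals) == expected == n_tiles(length, window, overlap)

    def test_fragment_sequences_match_source_slices(self, tetanus_sized_protein):
        frags = tile_protein(tetanus_sized_protein, 400, 30)
        for f in frags:
            assert f.sequence == tetanus_sized_protein.sequence[f.start - 1 : f.end]
            assert f.name == f"TetX_synthetic_{f.start}-{f.end}"


class TestSubstitutions:
    def test_single_deamidation_edit(self):
        p = ProteinRecord("glia", "QPQLPY")
        out = apply_substitutions(p, [SubstitutionSpec(3, "Q", "E")])
        assert out.sequence == "QPELPY"
        assert p.sequence == "QPQLPY"  # input untouched

    def test_empty_list_is_identity(self):
        p = ProteinRecord("glia", "QPQLPY")
        assert apply_substitutions(p, []).sequence == p.sequence

    def test_from_aa_mismatch_names_position(self):
        p = ProteinRecord("glia", "QPQLPY")
        with pytest.raises(ProvenanceError, match="position 4"):
            apply_substitutions(p, [SubstitutionSpec(4, "Q", "E")])

    def test_duplicate_positions_rejected(self):
        p = ProteinRecord("glia", "QPQLPY")
        subs = [SubstitutionSpec(3, "Q", "E"), SubstitutionSpec(3, "Q", "E")]
        with pytest.raises(InvalidInputError):
            apply_substitutions(p, subs)

    def test_edits_differ_only_at_positions(self):
        p = random_protein(200, seed=5)
        subs = [
            SubstitutionSpec(i, p.sequence[i - 1], "A" if p.sequence[i - 1] != "A" else "G")
            for i in (1, 100, 200)
        ]
        out = apply_substitutions(p, subs)
        diffs = [i + 1 for i, (a, b) in enumerate(zip(p.sequence, out.sequence)) if a != b]
        assert diffs == [1, 100, 200]


class TestAssembly:
    def test_leader_fusion_at_n_terminus(self):
        p = random_protein(400, seed=6)
        frag = fragment_from_interval(p, 1, 400)
        leader = "MVFLFLWK"
        c = assemble_construct([frag], leader=leader, leader_id="ST1")
        assert len(c) == 408
        assert c.assembled_sequence.startswith(leader)
        assert c.assembled_sequence.endswith(frag.sequence)

    def test_linker_only_between_fragments(self):
        p = random_protein(60, seed=7)
        f1 = fragment_from_interval(p, 1, 30)
        f2 = fragment_from_interval(p, 31, 60)
        c = assemble_construct([f1, f2], linker="GGGGS")
        assert len(c) == 65
        assert c.assembled_sequence == f1.sequence + "GGGGS" + f2.sequence

    def test_single_fragment_no_leader_is_identity(self):
        p = random_protein(50, seed=8)
        frag = fragment_from_interval(p, 1, 50)
        c = assemble_construct([frag])
        assert c.assembled_sequence == frag.sequence

    def test_empty_fragment_list_rejected(self):
        with pytest.raises(InvalidInputError):
            assemble_construct([])


class TestRefinement:
    def test_binary_split_of_400aa_fragment(self, tetanus_sized_protein):
        parent = fragment_from_interval(tetanus_sized_protein, 612, 1011)
        kids = refine_fragment(parent, n_children=2, min_overlap=30, min_length=20)
        assert [(k.fragment.start, k.fragment.end) for k in kids] == [
            (612, 826),
            (797, 1011),
        ]
        assert all(len(k.fragment) == 215 for k in kids)
        assert all(k.level == 1 for k in kids)

    def test_exhaustion_at_min_length(self):
        p = random_protein(20, seed=9)
        frag = fragment_from_interval(p, 1, 20)
        with pytest.raises(RefinementExhausted):
            refine_fragment(frag, n_children=2, min_overlap=5, min_length=20)

    def test_four_way_split_covers_parent(self):
        p = random_protein(100, seed=10)
        parent = fragment_from_interval(p, 1, 100)
        kids = refine_fragment(parent, n_children=4, min_overlap=10, min_length=20)
        assert len(kids) == 4
        assert all(len(k.fragment) <= 33 for k in kids)
        assert covered_residues([k.fragment for k in kids]) == set(range(1, 101))

    def test_recursive_refinement_terminates_and_covers(self, tetanus_sized_protein):
        """Refining to exhaustion always terminates; each level's leaves
        jointly cover the root interval."""
        root = fragment_from_interval(tetanus_sized_protein, 612, 1011)
        level = [RefinementNode(root)]
        root_interval = set(range(612, 1012))
        for _depth in range(20):
            nxt = []
            for node in level:
                try:
                    nxt.extend(refine_fragment(node, 2, min_overlap=15, min_length=20))
                except RefinementExhausted:
                    pass
            if not nxt:
                break
            assert covered_residues([n.fragment for n in nxt]) == root_interval
            for n in nxt:
                p = n.parent.fragment
                assert p.start <= n.fragment.start and n.fragment.end <= p.end
                assert len(n.fragment) < len(p)
            level = nxt
        else:
            pytest.fail("refinement did not terminate")

    def test_child_sequences_inherit_source_coordinates(self, tetanus_sized_protein):
        parent = fragment_from_interval(tetanus_sized_protein, 612, 1011)
        for kid in refine_fragment(parent, 3, min_overlap=20, min_length=20):
            f = kid.fragment
            assert f.sequence == tetanus_sized_protein.sequence[f.start - 1 : f.end]


class TestEpitopeInterval:
    def _node(self, start, end, level=1, outcome="positive", source="TetX"):
        seq = "A" * (end - start + 1)
        return RefinementNode(FragmentSpec(source, start, end, seq),
                              level=level, outcome=outcome)

    def test_intersection_of_overlapping_positives(self):
        nodes = [self._node(612, 826), self._node(797, 1011)]
        assert epitope_interval(nodes) == (797, 826)

    def test_single_positive_is_identity(self):
        assert epitope_interval([self._node(1, 400)]) == (1, 400)

    def test_disjoint_positives_signal_inconsistency(self):
        with pytest.raises(InconsistentEpitopes):
            epitope_interval([self._node(1, 100), self._node(200, 300)])

    def test_no_positives(self):
        with pytest.raises(NoPositiveFragments):
            epitope_interval([self._node(1, 100, outcome="negative")])

    def test_only_deepest_level_intersected(self):
        nodes = [
            self._node(1, 400, level=0),
            self._node(1, 215, level=1),
            self._node(186, 400, level=1),
        ]
        assert epitope_interval(nodes) == (186, 215)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 300), st.integers(0, 80)),
                    min_size=1, max_size=6))
    def test_matches_brute_force_intersection(self, raw):
        nodes = [self._node(s, s + w) for s, w in raw]
        lo = max(s for s, w in raw)
        hi = min(s + w for s, w in raw)
        brute = set(range(raw[0][0], raw[0][0] + raw[0][1] + 1))
        for s, w in raw[1:]:
            brute &= set(range(s, s + w + 1))
        if not brute:
            with pytest.raises(InconsistentEpitopes):
                epitope_interval(nodes)
        else:
            assert epitope_interval(nodes) == (lo, hi) == (min(brute), max(brute))
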