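import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wrkykit import classification as cl
from wrkykit import domain_scan, synthetic_data
from wrkykit.errors import ClassificationError, NumericalError, ValidationError
from wrkykit.io_formats import ProteinRecord

from .oracles import ls_best_topology, mw_oracle_kda, random_additive_tree


class TestGroupRule:
    def test_fixture_rows(self, family):
        by_name = {m.name: m for m in family}
        assert cl.classify_member(by_name["PmWRKY01"]) == "I"
        assert cl.classify_member(by_name["PmWRKY08"]) == "III"
        # PmWRKY51: single C2H2 domain -> II by rule; IIx is a subgroup call
        assert cl.classify_member(by_name["PmWRKY51"]) == "II"

    def test_groups_partition_family(self, family):
        counts = cl.family_summary(family).group_counts
        assert sum(counts.values()) == len(family)

    def test_zero_domains_is_error(self):
        with pytest.raises(ClassificationError):
            cl.classify_group([])

    def test_three_domains_flagged_for_review(self):
        with pytest.raises(ClassificationError):
            cl.group_rule(3, "C2H2")


class TestAlignment:
    def test_identity_alignment(self):
        assert cl.align_pair("WRKY", "WRKY") == ("WRKY", "WRKY")

    def test_single_gap_inserted(self):
        aa, bb = cl.align_pair("WRKY", "WKY")
        assert (aa, bb) == ("WRKY", "W-KY")

    def test_all_mismatch_no_gaps(self):
        aa, bb = cl.align_pair("AAAA", "GGGG")
        assert len(aa) == 4 and cl.p_distance(aa, bb) == 1.0

    def test_exhaustive_small_alignment_oracle(self):
        # all ungapped/gapped alignments of a 4 x 3 pair, scored directly
        a, b = "WRKY", "WKY"

        def score(x, y):
            s, in_gap = 0.0, False
            for u, v in zip(x, y):
                if u == "-" or v == "-":
                    s += -1.0 if in_gap else -5.0
                    in_gap = True
                else:
                    s += 1.0 if u == v else 0.0
                    in_gap = False
            return s

        def enum(x, y):
            if not x and not y:
                yield "", ""
                return
            if x and y:
                for u, v in enum(x[1:], y[1:]):
                    yield x[0] + u, y[0] + v
            if x:
                for u, v in enum(x[1:], y):
                    yield x[0] + u, "-" + v
            if y:
                for u, v in enum(x, y[1:]):
                    yield "-" + u, y[0] + v

        best = max(score(x, y) for x, y in enum(a, b))
        aa, bb = cl.align_pair(a, b)
        assert score(aa, bb) == best

    def test_p_distance_quarter(self):
        assert cl.p_distance("AAAA", "AAAT") == 0.25

    def test_p_distance_identical_zero(self):
        assert cl.p_distance("WRKY", "WRKY") == 0.0

    def test_all_gap_overlap_undefined(self):
        with pytest.raises(NumericalError):
            cl.p_distance("A--", "-AA")


class TestNeighborJoining:
    def test_three_point_branch_lengths(self):
        d = cl.DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = cl.build_nj_tree(d)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_additive_four_taxon_topology_recovered(self):
        rng = np.random.default_rng(42)
        from .oracles import topology_bipartitions

        edges, dist = random_additive_tree(4, rng)
        labels = [f"L{i}" for i in range(4)]
        tree = cl.build_nj_tree(cl.DistanceMatrix(labels, dist))
        got = {frozenset(int(x[1:]) for x in side) for side in tree.bipartitions()}
        assert got == topology_bipartitions(edges, 4)

    def test_nj_matches_exhaustive_ls_oracle(self):
        rng = np.random.default_rng(7)
        for n in (5, 6):
            edges, dist = random_additive_tree(n, rng)
            labels = [f"L{i}" for i in range(n)]
            tree = cl.build_nj_tree(cl.DistanceMatrix(labels, dist))
            got = {frozenset(int(x[1:]) for x in side) for side in tree.bipartitions()}
            assert got == ls_best_topology(dist)

    def test_nj_agrees_with_scikit_bio(self):
        # independent library cross-check on a random (non-additive) matrix
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        n = 6
        m = rng.uniform(0.2, 1.0, size=(n, n))
        dist = (m + m.T) / 2
        np.fill_diagonal(dist, 0.0)
        labels = [f"L{i}" for i in range(n)]
        ours = cl.build_nj_tree(cl.DistanceMatrix(labels, dist))
        theirs = skbio_nj(SkbioDM(dist, ids=labels))
        all_leaves = frozenset(labels)
        their_splits = set()
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if min(all_leaves) in side:
                side = all_leaves - side
            if 1 < len(side) < n - 1:
                their_splits.add(side)
        assert ours.bipartitions() == their_splits

    def test_all_zero_distances_give_zero_lengths(self):
        labels = list("abcde")
        tree = cl.build_nj_tree(cl.DistanceMatrix(labels, np.zeros((5, 5))))
        assert all(n.length == 0.0 for n in tree.nodes() if n is not tree.root)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            cl.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment(rng):
        protoA = "".join(rng.choice(list("ADEF"), 40))
        protoB = "".join(rng.choice(list("IKLM"), 40))

        def noisy(proto):
            s = list(proto)
            for i in rng.integers(0, 40, size=2):
                s[i] = "G"
            return "".join(s)

        return [(f"A{i}", noisy(protoA)) for i in range(3)] + [
            (f"B{i}", noisy(protoB)) for i in range(3)
        ]

    def test_separating_edge_strongly_supported(self):
        rng = np.random.default_rng(0)
        alignment = self._two_clade_alignment(rng)
        tree = cl.bootstrap_support(alignment, n_reps=100, seed=1)
        split = frozenset(["B0", "B1", "B2"])
        supports = {
            frozenset(l.name for l in node.leaves()): node.support
            for node in tree.nodes()
            if node.support is not None
        }
        matching = [
            s for side, s in supports.items() if side in (split,)
        ]
        assert matching and min(matching) >= 95.0

    def test_single_replicate_supports_are_all_or_nothing(self):
        rng = np.random.default_rng(5)
        alignment = self._two_clade_alignment(rng)
        tree = cl.bootstrap_support(alignment, n_reps=1, seed=2)
        values = {n.support for n in tree.nodes() if n.support is not None}
        assert values <= {0.0, 100.0}

    def test_identical_sequences_give_flat_tree(self):
        alignment = [(f"s{i}", "AAAA") for i in range(4)]
        tree = cl.bootstrap_support(alignment, n_reps=5, seed=3)
        assert all(
            n.length == 0.0 for n in tree.nodes() if n is not tree.root
        )


class TestSubgroupAssignment:
    @staticmethod
    def _tree_with_query(reference_set, query_seq, query_name="Q"):
        named = []
        for acc, _, seq in reference_set:
            (dom,) = (
                domain_scan.domain_sequences(ProteinRecord(acc, seq))[:1]
                or [seq]
            )
            named.append((acc, dom))
        named.append((query_name, query_seq))
        return cl.build_nj_tree(cl.DistanceMatrix.from_sequences(named))

    def test_perturbed_copy_recovers_reference_label(self, reference_set):
        rng = np.random.default_rng(17)
        acc, subgroup, seq = next(r for r in reference_set if r[1] == "IIa")
        (dom,) = domain_scan.domain_sequences(ProteinRecord(acc, seq))
        query = synthetic_data.perturb_sequence(dom, 0.08, rng)
        tree = self._tree_with_query(reference_set, query)
        refmap = {a: s for a, s, _ in reference_set}
        assert cl.assign_subgroup(tree, "Q", refmap) == "IIa"

    def test_distant_query_falls_back_to_iix(self, reference_set):
        rng = np.random.default_rng(23)
        query = "".join(rng.choice(list(synthetic_data.BACKGROUND_ALPHABET), 35))
        tree = self._tree_with_query(reference_set, query)
        refmap = {a: s for a, s, _ in reference_set}
        assert cl.assign_subgroup(tree, "Q", refmap) == "IIx"

    def test_fixture_iix_label(self, family):
        assert next(m for m in family if m.name == "PmWRKY51").subgroup == "IIx"

    def test_query_not_in_tree_is_error(self, reference_set):
        rng = np.random.default_rng(2)
        tree = self._tree_with_query(reference_set, "WRKYGQK" + "A" * 20)
        with pytest.raises(ValidationError):
            cl.assign_subgroup(tree, "missing", {a: s for a, s, _ in reference_set})


class TestProteinStats:
    def test_glycine_mass(self):
        assert cl.protein_mw("G") == pytest.approx(0.07507, abs=1e-4)
        assert round(cl.protein_mw("G"), 2) == 0.08

    def test_diglycine_mass_da(self):
        assert cl.protein_mw("GG") * 1000 == pytest.approx(132.12, abs=0.01)

    def test_empty_and_x_rejected(self):
        with pytest.raises(ValidationError):
            cl.protein_mw("")
        with pytest.raises(ValidationError):
            cl.protein_mw("AXA")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_mw_matches_hand_mass_table(self, seq):
        assert cl.protein_mw(seq) == pytest.approx(mw_oracle_kda(seq), rel=1e-4)

    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=15),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=15),
    )
    def test_mw_additivity(self, a, b):
        water = 18.0153 / 1000.0
        assert cl.protein_mw(a + b) == pytest.approx(
            cl.protein_mw(a) + cl.protein_mw(b) - water, rel=1e-6
        )

    def test_basic_peptide_has_high_pi(self):
        pi = cl.protein_pi("K" * 10)
        assert pi > 9
        assert cl.net_charge("K" * 10, 9.0) > 0  # sign-check oracle

    def test_acidic_peptide_has_low_pi(self):
        pi = cl.protein_pi("D" * 10)
        assert pi < 5
        assert cl.net_charge("D" * 10, 5.0) < 0

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=25))
    def test_pi_is_charge_root(self, seq):
        assert abs(cl.net_charge(seq, cl.protein_pi(seq))) < 1e-4

    @given(st.text(alphabet="ACDEFGLMNPQSTV", min_size=2, max_size=15))
    def test_pi_monotone_under_residue_swaps(self, seq):
        assert cl.protein_pi("K" + seq) >= cl.protein_pi("G" + seq)
        assert cl.protein_pi("D" + seq) <= cl.protein_pi("G" + seq)

    def test_pi_close_to_biopython_reference(self):
        # independent implementation of the same pKa model
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        for seq in ("WRKYGQK", "ACDKRH", "MKLVINE"):
            theirs = IsoelectricPoint(seq).pi()
            assert cl.protein_pi(seq) == pytest.approx(theirs, abs=0.1)


class TestFamilySummary:
    def test_group_counts(self, family):
        s = cl.family_summary(family)
        assert s.group_counts == {"I": 10, "II": 40, "III": 8}

    def test_subgroup_counts(self, family):
        s = cl.family_summary(family)
        assert s.subgroup_counts == {
            "I": 10, "IIa": 3, "IIb": 9, "IIc": 14, "IId": 6, "IIe": 7,
            "IIx": 1, "III": 8,
        }

    def test_printed_ranges(self, family):
        s = cl.family_summary(family)
        assert s.length_range == (162, 884)
        assert s.mw_range == (18.46, 98.18)
        assert s.pi_range == (4.90, 9.68)

    def test_two_variant_heptapeptides(self, family):
        s = cl.family_summary(family)
        assert s.n_variant_heptapeptide == 2
        variants = {m.name for m in family if m.heptapeptide == "WRKYGKK"}
        assert variants == {"PmWRKY04", "PmWRKY16"}
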