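"""Alignment, mutation identification, BLOSUM62, and the comparison network."""

import numpy as np
import pytest

from rinmap import (
    PairwiseAlignment,
    blosum62,
    build_comparison_network,
    build_rin,
    find_mutations,
    fixtures,
    global_align,
    read_aligned_fasta,
    unchanged_fraction,
    write_aligned_fasta,
)
from rinmap.comparison import alignment_score
from rinmap.rin_builder import RIN

from conftest import gotoh_score


class TestBlosum62:
    @pytest.mark.parametrize("x, y, expected", [("W", "W", 11), ("A", "A", 4), ("L", "K", -2)])
    def test_published_values(self, x, y, expected):
        assert blosum62(x, y) == expected

    def test_symmetric_over_full_alphabet(self):
        alphabet = "ARNDCQEGHILKMFPSTWYVBZX*"
        assert len(alphabet) == 24
        for x in alphabet:
            for y in alphabet:
                assert blosum62(x, y) == blosum62(y, x)

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            blosum62("A", "U")


class TestGlobalAlign:
    def test_identity_alignment_no_gaps(self):
        aln = global_align("ACDE", "ACDE")
        assert aln.rows == ("ACDE", "ACDE")
        assert aln.n_columns == 4

    def test_single_deletion(self):
        # exhaustive check at this size: the only optimal alignment under
        # open -10 / extend -1 deletes the D column
        aln = global_align("ACDE", "ACE")
        assert aln.rows[0] == "ACDE"
        assert aln.rows[1].count("-") == 1
        assert alignment_score(aln) == gotoh_score("ACDE", "ACE")

    @pytest.mark.parametrize("seed", range(8))
    def test_returned_score_is_dp_optimum(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(alphabet, size=int(rng.integers(5, 25))))
        b = "".join(rng.choice(alphabet, size=int(rng.integers(5, 25))))
        aln = global_align(a, b)
        assert alignment_score(aln) == pytest.approx(gotoh_score(a, b))

    def test_self_alignment_scores_diagonal_sum(self):
        seq = "MKTAYIAK"
        aln = global_align(seq, seq)
        assert "-" not in aln.rows[0] + aln.rows[1]
        assert alignment_score(aln) == sum(blosum62(c, c) for c in seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACDE")


class TestFindMutations:
    def test_substitution_column(self):
        ms = find_mutations(PairwiseAlignment("a", "b", ("ACDE", "ACFE")))
        assert len(ms.substitutions) == 1
        col, aa_a, aa_b, *_ , score = ms.substitutions[0]
        assert (col, aa_a, aa_b) == (3, "D", "F")
        assert score == blosum62("D", "F")

    def test_insertion_in_b(self):
        ms = find_mutations(PairwiseAlignment("a", "b", ("AC-E", "ACFE")))
        assert ms.insertions_in_b == [3]
        assert not ms.substitutions and not ms.deletions_from_a

    def test_identity_is_empty(self):
        ms = find_mutations(PairwiseAlignment("a", "b", ("ACDE", "ACDE")))
        assert ms.n_changes == 0

    def test_double_gap_rejected(self):
        with pytest.raises(ValueError):
            find_mutations(PairwiseAlignment("a", "b", ("A-DE", "A-DE")))


def _toy_rin(edge_list, n=4, chain="A"):
    r = RIN(name="toy")
    for i in range(1, n + 1):
        r.add_node(str(i), chain=chain, seq_num=i, aa1="A", ss_segment="")
    for u, v in edge_list:
        r.add_edge(str(u), str(v), "contact", "mc_mc", 1)
    return r


def _identity_alignment(n):
    aln = PairwiseAlignment("a", "b", ("A" * n, "A" * n))
    ids = [str(i) for i in range(1, n + 1)]
    aln.attach_node_ids(ids, ids)
    return aln


class TestComparisonNetwork:
    def test_self_comparison_all_conserved(self, helix12, helix_rin):
        ids = [r.node_id for r in helix12.residues]
        aln = PairwiseAlignment("a", "b", (helix12.sequence("A"), helix12.sequence("A")))
        aln.attach_node_ids(ids, ids)
        cn = build_comparison_network(helix_rin, helix_rin, aln)
        counts = cn.status_counts()
        assert counts["lost"] == counts["gained"] == 0
        assert counts["conserved"] == len(helix_rin.residue_pairs())
        assert cn.graph.number_of_nodes() == helix_rin.graph.number_of_nodes()
        for n in cn.graph.nodes:
            assert cn.graph.nodes[n]["unchanged_fraction"] == 1.0

    def test_enumerated_toy_statuses(self):
        rin_a = _toy_rin([(1, 3), (2, 4)])
        rin_b = _toy_rin([(1, 3), (1, 4)])
        cn = build_comparison_network(rin_a, rin_b, _identity_alignment(4))
        assert cn.edges_with_status("conserved") == [(1, 3)]
        assert cn.edges_with_status("lost") == [(2, 4)]
        assert cn.edges_with_status("gained") == [(1, 4)]
        assert unchanged_fraction(cn, 1) == pytest.approx(0.5)

    def test_empty_mutant_loses_everything(self):
        rin_a = _toy_rin([(1, 2), (1, 3), (2, 4)])
        rin_b = _toy_rin([])
        cn = build_comparison_network(rin_a, rin_b, _identity_alignment(4))
        counts = cn.status_counts()
        assert counts == {"conserved": 0, "lost": 3, "gained": 0}

    @pytest.mark.parametrize("seed", range(20))
    def test_bookkeeping_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        all_pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
        pick = lambda: [all_pairs[k] for k in rng.choice(len(all_pairs),
                        size=min(len(all_pairs), int(rng.integers(1, 3 * n))), replace=False)]
        rin_a = _toy_rin(pick(), n=n)
        rin_b = _toy_rin(pick(), n=n)
        aln = _identity_alignment(n)
        cn = build_comparison_network(rin_a, rin_b, aln)
        c = cn.status_counts()
        assert c["conserved"] + c["lost"] == len(rin_a.residue_pairs())
        assert c["conserved"] + c["gained"] == len(rin_b.residue_pairs())
        # swapping inputs swaps lost and gained, conserves the rest
        cn_sw = build_comparison_network(rin_b, rin_a, aln)
        assert cn_sw.edges_with_status("lost") == cn.edges_with_status("gained")
        assert cn_sw.edges_with_status("gained") == cn.edges_with_status("lost")
        assert cn_sw.edges_with_status("conserved") == cn.edges_with_status("conserved")
        for node in cn.graph.nodes:
            assert unchanged_fraction(cn_sw, node) == unchanged_fraction(cn, node)

    def test_isolated_node_scores_one(self):
        cn = build_comparison_network(_toy_rin([(1, 2)]), _toy_rin([(1, 2)]),
                                      _identity_alignment(4))
        # nodes 3 and 4 have no incident comparison edges
        assert unchanged_fraction(cn, 3) == 1.0

    def test_unaligned_columns_flagged(self, helix12):
        r = build_rin(helix12)
        spec = fixtures.MutationSpec(substitutions=[(3, "W")], deletions=[7],
                                     insertions=[(9, "G")])
        _, seq_b, aln = fixtures.make_mutant_pair(helix12, spec)
        rin_b = RIN(name="mut")  # mutant network: empty, nodes come from A
        cn = build_comparison_network(r, rin_b, aln)
        flagged = {n for n in cn.graph.nodes if cn.graph.nodes[n]["unaligned"]}
        muts = find_mutations(aln)
        assert flagged <= set(muts.deletions_from_a) | set(muts.insertions_in_b)
        mutated = {n for n in cn.graph.nodes if cn.graph.nodes[n]["mutated"]}
        assert mutated == {m[0] for m in muts.substitutions}

    def test_uncovered_rin_node_is_error(self):
        rin_a = _toy_rin([(1, 5)], n=5)
        aln = _identity_alignment(4)  # node 5 missing from the column map
        with pytest.raises(ValueError, match="5"):
            build_comparison_network(rin_a, _toy_rin([], n=4), aln)


class TestAlignedFastaIO:
    def test_round_trip(self, tmp_path):
        aln = PairwiseAlignment("parent", "mutant", ("ACD-E", "ACDFE"))
        p = tmp_path / "aln.fasta"
        write_aligned_fasta(aln, p)
        aln2 = read_aligned_fasta(p)
        assert aln2.rows == aln.rows
        assert (aln2.id_a, aln2.id_b) == ("parent", "mutant")

    def test_wrong_record_count_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">only\nACDE\n")
        with pytest.raises(ValueError):
            read_aligned_fasta(p)
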