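"""RIN construction against a brute-force oracle, plus SIF/TSV interchange."""

import numpy as np
import pytest

from rinmap import build_rin, extract_interface, fixtures, read_rin, write_rin
from rinmap.structure_io import Atom, Residue, Structure

from conftest import brute_force_rin_pairs


def _two_residue_structure(gap, chains=("A", "A"), seq_nums=(1, 2)):
    """Two single-CA residues whose CA atoms are `gap` Å apart."""
    r1 = Residue(chains[0], seq_nums[0], "", "ALA",
                 [Atom("CA", "C", np.zeros(3))])
    r2 = Residue(chains[1], seq_nums[1], "", "ALA",
                 [Atom("CA", "C", np.array([gap, 0.0, 0.0]))])
    return Structure(id="pair", chains=sorted(set(chains)), residues=[r1, r2])


class TestBuildRin:
    def test_sequence_neighbors_excluded(self):
        s = _two_residue_structure(4.0)
        r = build_rin(s, contact_cutoff=5.0, exclude_neighbors=1)
        assert r.number_of_edges() == 0

    def test_exclusion_is_same_chain_only(self):
        s = _two_residue_structure(4.0, chains=("A", "B"), seq_nums=(1, 1))
        r = build_rin(s, contact_cutoff=5.0, exclude_neighbors=1)
        assert r.residue_pairs("contact") == {("A:1:_:ALA", "B:1:_:ALA")}

    @pytest.mark.parametrize(
        "make",
        [
            lambda: fixtures.make_helix(12),
            lambda: fixtures.make_helix(12, with_cb=True),
            lambda: fixtures.make_strand(10),
            lambda: fixtures.make_two_strands(),
            lambda: fixtures.make_dimer(5, [(2, 2), (3, 4)]),
            lambda: fixtures.make_random_coil(25, seed=7),
        ],
        ids=["helix", "helix_cb", "strand", "two_strands", "dimer", "coil"],
    )
    def test_matches_brute_force_oracle(self, make):
        s = make()
        r = build_rin(s)
        contacts, hbonds = brute_force_rin_pairs(s)
        assert r.residue_pairs("contact") == set(contacts)
        assert r.residue_pairs("hbond") == set(hbonds)
        for u, v, itype, data in r.edges():
            ref = contacts if itype == "contact" else hbonds
            assert data["natom_pairs"] == ref[(u, v)]

    def test_monotone_in_contact_cutoff(self):
        s = fixtures.make_random_coil(20, seed=3)
        prev = set()
        for cutoff in (4.0, 5.0, 6.5, 8.0):
            edges = build_rin(s, contact_cutoff=cutoff, hbond_cutoff=3.5).residue_pairs("contact")
            assert prev <= edges
            prev = edges

    def test_monotone_in_neighbor_exclusion(self):
        s = fixtures.make_helix(15)
        prev = None
        for k in (0, 1, 2, 3):
            edges = build_rin(s, exclude_neighbors=k).residue_pairs()
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_symmetric_under_residue_reversal(self, helix12):
        fwd = build_rin(helix12).residue_pairs()
        rev = Structure(
            id="rev",
            chains=list(helix12.chains),
            residues=list(reversed(helix12.residues)),
        )
        assert build_rin(rev).residue_pairs() == fwd

    def test_hbond_subset_of_contacts(self):
        s = fixtures.make_helix(14)
        r = build_rin(s, contact_cutoff=5.0, hbond_cutoff=3.5)
        assert r.residue_pairs("hbond") <= r.residue_pairs("contact")

    def test_subtype_reflects_atom_classes(self):
        s = fixtures.make_helix(12, with_cb=True)
        r = build_rin(s)
        subtypes = {d["subtype"] for _, _, _, d in r.edges()}
        assert subtypes <= {"mc_mc", "mc_sc", "sc_sc"}
        # backbone-only structures can never produce sidechain contacts
        r2 = build_rin(fixtures.make_helix(12))
        assert {d["subtype"] for *_, d in r2.edges()} == {"mc_mc"}

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            build_rin(Structure(id="x", chains=[], residues=[]))

    def test_bad_cutoffs_rejected(self, helix12):
        with pytest.raises(ValueError):
            build_rin(helix12, contact_cutoff=-1.0)
        with pytest.raises(ValueError):
            build_rin(helix12, contact_cutoff=4.0, hbond_cutoff=5.0)


class TestInterface:
    def test_no_cross_chain_edges(self):
        d = fixtures.make_dimer(4, [])
        iface = extract_interface(build_rin(d), "A", "B")
        assert iface.number_of_edges() == 0

    def test_designed_contacts_recovered(self, dimer):
        iface = extract_interface(build_rin(dimer), "A", "B")
        assert iface.residue_pairs() == {
            ("A:2:_:VAL", "B:2:_:VAL"),
            ("A:3:_:LEU", "B:4:_:SER"),
        }
        assert iface.graph.number_of_nodes() <= 6
        for u, v, *_ in iface.edges():
            assert {iface.graph.nodes[u]["chain"], iface.graph.nodes[v]["chain"]} == {"A", "B"}

    def test_same_chain_rejected(self, dimer):
        with pytest.raises(ValueError):
            extract_interface(build_rin(dimer), "A", "A")

    def test_unknown_chain_rejected(self, dimer):
        with pytest.raises(ValueError):
            extract_interface(build_rin(dimer), "A", "Z")

    def test_symmetric_in_chain_order(self, dimer):
        r = build_rin(dimer)
        assert (
            extract_interface(r, "A", "B").residue_pairs()
            == extract_interface(r, "B", "A").residue_pairs()
        )


class TestSifInterchange:
    def test_round_trip_preserves_everything(self, tmp_path, helix_rin):
        sif, attrs = tmp_path / "h.sif", tmp_path / "h.attrs.tsv"
        write_rin(helix_rin, sif, attrs)
        r2 = read_rin(sif, attrs)
        assert set(r2.graph.nodes) == set(helix_rin.graph.nodes)
        assert r2.edges() == helix_rin.edges()
        for n in helix_rin.graph.nodes:
            assert dict(r2.graph.nodes[n]) == dict(helix_rin.graph.nodes[n])

    def test_sif_line_parses_to_contact_edge(self, tmp_path):
        sif = tmp_path / "e.sif"
        attrs = tmp_path / "e.tsv"
        sif.write_text("A:4:_:ALA\tcnt:sc_sc\tA:8:_:LEU\n")
        attrs.write_text(
            "node_id\tchain\tseq_num\taa1\tss_segment\n"
            "A:4:_:ALA\tA\t4\tA\t\nA:8:_:LEU\tA\t8\tL\t\n"
        )
        r = read_rin(sif, attrs)
        edges = r.edges()
        assert len(edges) == 1
        u, v, itype, data = edges[0]
        assert (itype, data["subtype"]) == ("contact", "sc_sc")

    def test_unknown_label_is_error_with_line(self, tmp_path):
        sif = tmp_path / "bad.sif"
        attrs = tmp_path / "bad.tsv"
        sif.write_text("A:1:_:ALA\txyz:mc_mc\tA:3:_:ALA\n")
        attrs.write_text(
            "node_id\tchain\tseq_num\taa1\tss_segment\n"
            "A:1:_:ALA\tA\t1\tA\t\nA:3:_:ALA\tA\t3\tA\t\n"
        )
        with pytest.raises(ValueError, match=":1:"):
            read_rin(sif, attrs)

    def test_node_missing_from_attr_table_is_error(self, tmp_path):
        sif = tmp_path / "m.sif"
        attrs = tmp_path / "m.tsv"
        sif.write_text("A:1:_:ALA\tcnt:mc_mc\tA:3:_:ALA\n")
        attrs.write_text("node_id\tchain\tseq_num\taa1\tss_segment\nA:1:_:ALA\tA\t1\tA\t\n")
        with pytest.raises(ValueError, match="A:3:_:ALA"):
            read_rin(sif, attrs)
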