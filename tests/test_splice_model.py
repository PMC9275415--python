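"""Splice-graph construction, isoform enumeration, translation, and junction PSI."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from spliceprm import gene_models
from spliceprm.errors import (
    GraphStructureError,
    SequenceFormatError,
    UndefinedRatioError,
    UnknownSegmentError,
)
from spliceprm.splice_model import (
    Exon,
    build_splice_graph,
    enumerate_isoforms,
    junction_psi,
    proteoforms_to_fasta,
    read_exon_table,
    translate_isoform,
)


def _toy_records():
    return [
        {"exon_id": "23", "sequence": "ATGAAA", "kind": "constitutive"},
        {"exon_id": "24", "sequence": "GGGTTT", "kind": "alternative"},
        {"exon_id": "25a", "sequence": "AAATTT", "kind": "alternative_acceptor",
         "acceptor_label": "25a"},
        {"exon_id": "25b", "sequence": "CCCTTT", "kind": "alternative_acceptor",
         "acceptor_label": "25b"},
        {"exon_id": "25c", "sequence": "GGGCCC", "kind": "alternative_acceptor",
         "acceptor_label": "25c"},
    ]


class TestBuildGraph:
    def test_three_exon_toy_has_one_acceptor_group_of_size_three(self):
        graph = build_splice_graph(_toy_records(), gene_id="toy")
        assert len(graph.acceptor_runs()) == 1
        assert set(graph.acceptor_groups) == {"25a", "25b", "25c"}
        assert graph.alternative_exons == ("24",)

    def test_single_constitutive_exon_gives_empty_segments(self):
        graph = build_splice_graph(
            [{"exon_id": "e1", "sequence": "ATGAAA", "kind": "constitutive"}]
        )
        assert graph.segments == {}
        assert len(enumerate_isoforms(graph)) == 1

    def test_duplicate_exon_id_rejected(self):
        records = _toy_records()
        records.append(dict(records[0]))
        with pytest.raises(GraphStructureError, match="duplicate"):
            build_splice_graph(records)

    def test_non_dna_sequence_rejected(self):
        with pytest.raises(SequenceFormatError):
            build_splice_graph(
                [{"exon_id": "e1", "sequence": "ACGX", "kind": "constitutive"}]
            )

    def test_segment_naming_unknown_exon_rejected(self):
        with pytest.raises(GraphStructureError):
            build_splice_graph(_toy_records(), segments={"AS5": ("nope",)})

    def test_exon_table_csv_roundtrip(self, tmp_path):
        path = tmp_path / "exons.csv"
        path.write_text(
            "exon_id,kind,acceptor_label,sequence\n"
            "23,constitutive,,ATGAAA\n25a,alternative_acceptor,25a,AAATTT\n"
        )
        exons = read_exon_table(path)
        graph = build_splice_graph(exons, gene_id="toy")
        assert [e.exon_id for e in graph.exons] == ["23", "25a"]
        assert graph.acceptor_groups == {"25a": "25a"}


class TestEnumerate:
    def test_as5_toy_graph_yields_six_isoforms(self, toy_graph):
        assert len(enumerate_isoforms(toy_graph)) == 6

    def test_constraining_exon24_included_yields_three(self, toy_graph):
        isos = enumerate_isoforms(toy_graph, {"e24": True})
        assert len(isos) == 3
        assert all("e24" in iso.exon_path for iso in isos)

    def test_constraint_on_acceptor_label(self, toy_graph):
        isos = enumerate_isoforms(toy_graph, {"25a": True})
        assert len(isos) == 2
        assert all("e25a" in iso.exon_path for iso in isos)

    def test_unknown_constraint_rejected(self, toy_graph):
        with pytest.raises(UnknownSegmentError):
            enumerate_isoforms(toy_graph, {"exon99": True})

    def test_output_deterministically_ordered(self, toy_graph):
        paths = [iso.exon_path for iso in enumerate_isoforms(toy_graph)]
        assert paths == sorted(paths)

    @given(
        n_alt=st.integers(0, 4),
        acceptor_sizes=st.lists(st.integers(1, 3), max_size=2),
    )
    @settings(max_examples=30, deadline=None)
    def test_isoform_count_matches_combinatorial_product(self, n_alt, acceptor_sizes):
        """Count = 2^(#cassette exons) x product of acceptor-run sizes."""
        records = [{"exon_id": "first", "sequence": "ATGGAA", "kind": "constitutive"}]
        for i in range(n_alt):
            records.append(
                {"exon_id": f"alt{i}", "sequence": "GCTGCT", "kind": "alternative"}
            )
            records.append(
                {"exon_id": f"c{i}", "sequence": "GGTGGT", "kind": "constitutive"}
            )
        for j, size in enumerate(acceptor_sizes):
            for m in range(size):
                records.append(
                    {
                        "exon_id": f"acc{j}_{m}",
                        "sequence": "ACTACT",
                        "kind": "alternative_acceptor",
                        "acceptor_label": f"g{j}{m}",
                    }
                )
            records.append(
                {"exon_id": f"after{j}", "sequence": "CATCAT", "kind": "constitutive"}
            )
        graph = build_splice_graph(records)
        expected = 2 ** n_alt
        for size in acceptor_sizes:
            expected *= size
        assert len(enumerate_isoforms(graph)) == expected


class TestTranslate:
    def test_exon24_path_truncates_to_gpi_anchored(self, toy_graph):
        iso = [
            i for i in enumerate_isoforms(toy_graph) if "e24" in i.exon_path
        ][0]
        pf = translate_isoform(iso, toy_graph)
        assert pf.anchor_class == "gpi_anchored"
        # the sequence stops inside exon 24, before any exon-25 content
        assert set(pf.residue_exons) == {"e22", "e23", "e24"}

    def test_25a_without_exon24_is_translationally_silenced(self, toy_graph):
        iso = [
            i
            for i in enumerate_isoforms(toy_graph)
            if "e25a" in i.exon_path and "e24" not in i.exon_path
        ][0]
        pf = translate_isoform(iso, toy_graph)
        assert pf.anchor_class == "acceptor25a_silenced"
        assert pf.translation_efficiency < 1.0

    def test_constitutive_path_is_full_length_transmembrane(self, toy_graph):
        iso = [
            i
            for i in enumerate_isoforms(toy_graph)
            if "e25c" in i.exon_path and "e24" not in i.exon_path
        ][0]
        pf = translate_isoform(iso, toy_graph)
        assert pf.anchor_class == "transmembrane"
        assert pf.segment_inclusion["25c"]

    def test_gpi_shorter_than_transmembrane_of_same_upstream_path(self, toy_proteoforms):
        gpi = [p for p in toy_proteoforms if p.anchor_class == "gpi_anchored"]
        tm = [p for p in toy_proteoforms if p.anchor_class == "transmembrane"]
        assert gpi and tm
        assert all(
            len(g.aa_sequence) < len(t.aa_sequence) for g in gpi for t in tm
        )

    def test_translation_deterministic_and_idempotent(self, toy_graph):
        iso = enumerate_isoforms(toy_graph)[0]
        a = translate_isoform(iso, toy_graph)
        b = translate_isoform(iso, toy_graph)
        assert a == b

    def test_delta_ex24_rerouting_identity(self, toy_graph):
        """Deleting the cassette exon removes GPI proteoforms and maps every
        former AS5+ path onto the matching acceptor path of the reduced graph."""
        reduced = toy_graph.without_exon("e24")
        reduced_pfs = [translate_isoform(i, reduced) for i in enumerate_isoforms(reduced)]
        assert all(p.anchor_class != "gpi_anchored" for p in reduced_pfs)
        former_as5 = [
            i for i in enumerate_isoforms(toy_graph) if "e24" in i.exon_path
        ]
        reduced_paths = {i.exon_path for i in enumerate_isoforms(reduced)}
        for iso in former_as5:
            rerouted = tuple(e for e in iso.exon_path if e != "e24")
            assert rerouted in reduced_paths
        # the AS5+/25a cells re-route to the silenced acceptor-25a proteoform
        silenced = [p for p in reduced_pfs if p.anchor_class == "acceptor25a_silenced"]
        assert len(silenced) == 1
        assert silenced[0].segment_inclusion["25a"]

    def test_too_short_cds_raises(self):
        graph = build_splice_graph(
            [{"exon_id": "e1", "sequence": "AT", "kind": "constitutive"}]
        )
        from spliceprm.errors import TranslationError

        with pytest.raises(TranslationError):
            translate_isoform(enumerate_isoforms(graph)[0], graph)


class TestJunctionPsi:
    def test_mixed_junction_counts_follow_documented_averaging(self, toy_graph):
        counts = {("e23", "e24"): 50, ("e24", "e25a"): 50, ("e23", "e25b"): 100}
        assert junction_psi(toy_graph, counts, "e24") == pytest.approx(1 / 3)

    def test_zero_exclusion_reads_give_full_inclusion(self, toy_graph):
        counts = {("e23", "e24"): 10, ("e24", "e25a"): 12}
        assert junction_psi(toy_graph, counts, "e24") == 1.0

    def test_all_zero_counts_raise(self, toy_graph):
        with pytest.raises(UndefinedRatioError):
            junction_psi(toy_graph, {("e23", "e24"): 0, ("e23", "e25b"): 0}, "e24")

    def test_segment_label_resolves_to_its_cassette_exon(self, toy_graph):
        counts = {("e23", "e24"): 30, ("e23", "e25c"): 30}
        assert junction_psi(toy_graph, counts, "AS5") == pytest.approx(0.5)


def test_fasta_export_carries_class_and_inclusion_flags(tmp_path, toy_proteoforms):
    from Bio import SeqIO

    path = tmp_path / "proteoforms.fasta"
    proteoforms_to_fasta(toy_proteoforms, path)
    records = list(SeqIO.parse(str(path), "fasta"))
    assert len(records) == len(toy_proteoforms)
    assert any("anchor=gpi_anchored" in r.description for r in records)
    assert all("25a=" in r.description for r in records)
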