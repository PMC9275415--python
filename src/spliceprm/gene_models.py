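"""A compact Nrxn3 AS5-style example gene used throughout tests and examples.

The real AS5 segment of Nrxn3 spans exons 23-25, with the cassette exon 24
carrying a premature stop codon followed by a GPI omega-site-like motif, and
with three alternative acceptors (25a/25b/25c) in exon 25.  The example gene
reproduces that architecture at miniature scale with synthetic sequences
(the exon sequences are constructed, not the genomic Nrxn3 sequence):

* two upstream constitutive exons supplying constitutive reference peptides,
* a cassette exon (``e24``) encoding a stop codon and a small-omega,
  hydrophobic C-terminus (the GPI-anchored proteoform),
* an acceptor trio ``25a``/``25b``/``25c`` whose ``25a`` choice marks a
  translationally silenced proteoform,
* a downstream constitutive exon.

Exon boundaries are codon-aligned, so splice-junction peptides arise
naturally from digestion of full proteoform sequences.
"""

from __future__ import annotations

from .splice_model import (
    Exon,
    Proteoform,
    SpliceGraph,
    build_splice_graph,
    enumerate_isoforms,
    translate_isoform,
)

# One fixed codon per amino acid keeps back-translation deterministic.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def _cds(aa: str, stop: bool = False) -> str:
    return "".join(_CODON[a] for a in aa) + ("TAA" if stop else "")


# Amino-acid design of the example exons.  Constitutive peptides live
# upstream of the cassette exon so that they are present in every proteoform
# including the truncated GPI form.
_E22_AA = "MAGELVKDSTFNIPERVLQTAYEK"   # constitutive: MAGELVK / DSTFNIPER / VLQTAYEK
_E23_AA = "SSIDGTERLNPADT"             # constitutive SSIDGTER + junction prefix LNPADT
_E24_AA = "VGSEYKGIAVLS"               # cassette exon; stop codon appended below
_E25A_AA = "AGNETQSIR"                 # acceptor a (silencing)
_E25B_AA = "VTSEIR"                    # acceptor b
_E25C_AA = "QDFLGK"                    # acceptor c
_E26_AA = "STPDLGHIKAVYNDQSR"          # downstream constitutive

CONSTITUTIVE_PEPTIDES = ("MAGELVK", "DSTFNIPER", "VLQTAYEK", "SSIDGTER")
SEGMENT_PEPTIDES = {
    "AS5+": "LNPADTVGSEYK",      # spans the e23|e24 junction
    "25a": "LNPADTAGNETQSIR",    # spans the e23|e25a junction
    "25b": "LNPADTVTSEIR",
    "25c": "LNPADTQDFLGK",
}
ACCEPTOR_LABELS = frozenset({"25a", "25b", "25c"})


def as5_exon_records() -> list[Exon]:
    return [
        Exon("e22", _cds(_E22_AA), "constitutive"),
        Exon("e23", _cds(_E23_AA), "constitutive"),
        Exon("e24", _cds(_E24_AA, stop=True), "alternative"),
        Exon("e25a", _cds(_E25A_AA), "alternative_acceptor", "25a"),
        Exon("e25b", _cds(_E25B_AA), "alternative_acceptor", "25b"),
        Exon("e25c", _cds(_E25C_AA), "alternative_acceptor", "25c"),
        Exon("e26", _cds(_E26_AA, stop=True), "constitutive"),
    ]


def as5_toy_graph() -> SpliceGraph:
    """The example AS5 splice graph (6 transcript isoforms)."""
    return build_splice_graph(
        as5_exon_records(),
        gene_id="Nrxn3",
        segments={"AS5": ("e24", "e25a", "e25b", "e25c")},
    )


def as5_proteoforms(graph: SpliceGraph | None = None) -> list[Proteoform]:
    graph = graph or as5_toy_graph()
    return [translate_isoform(iso, graph) for iso in enumerate_isoforms(graph)]


def as5_proteoforms_by_name(graph: SpliceGraph | None = None) -> dict[str, Proteoform]:
    """Map the biologically meaningful proteoform classes to short names.

    The three exon-24-containing transcripts yield the same truncated
    GPI-anchored protein sequence; one representative is kept under ``gpi``.
    """
    named: dict[str, Proteoform] = {}
    for pf in as5_proteoforms(graph):
        if pf.anchor_class == "gpi_anchored":
            named.setdefault("gpi", pf)
        elif pf.anchor_class == "acceptor25a_silenced":
            named["silenced_25a"] = pf
        elif pf.segment_inclusion.get("25b"):
            named["tm_25b"] = pf
        elif pf.segment_inclusion.get("25c"):
            named["tm_25c"] = pf
    return named
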