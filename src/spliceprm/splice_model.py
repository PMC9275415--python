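"""Splice-graph model of a gene with alternative exons and acceptor sites.

The model captures the minimal architecture needed for proteoform-level
quantification of a neurexin-style alternatively spliced segment: an ordered
run of exons, of which some are constitutive, some are cassette (alternative)
exons, and some form a group of mutually exclusive alternative acceptor sites
(e.g. the 25a/25b/25c acceptors downstream of the alternative exon 24 in the
Nrxn3 AS5 segment).  Transcript isoforms are enumerated combinatorially and
translated into proteoforms.  A cassette exon may carry a premature stop
codon; if the resulting C-terminus matches a configurable GPI omega-site
motif rule the proteoform is classified as GPI-anchored.  Transcripts that
splice into a "silencing" acceptor (25a by default) without the cassette exon
are classified as translationally silenced and carry a reduced translation
efficiency.

Exons carry their own nucleotide sequences; genomic coordinates are
deliberately not modelled.
"""

from __future__ import annotations

import csv
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import (
    GraphStructureError,
    SequenceFormatError,
    TranslationError,
    UndefinedRatioError,
    UnknownSegmentError,
)

EXON_KINDS = ("constitutive", "alternative", "alternative_acceptor")
_DNA_RE = re.compile(r"^[ACGT]+$")

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class Exon:
    exon_id: str
    sequence: str
    kind: str
    acceptor_label: str | None = None


@dataclass(frozen=True)
class SpliceGraph:
    """Ordered exon architecture of one gene.

    ``acceptor_groups`` maps acceptor site labels (e.g. ``"25a"``) to the
    exon implementing that acceptor; consecutive acceptor exons are mutually
    exclusive.  ``segments`` maps segment labels (e.g. ``"AS5"``) to the exon
    ids the segment governs.
    """

    gene_id: str
    exons: tuple[Exon, ...]
    acceptor_groups: Mapping[str, str]
    segments: Mapping[str, tuple[str, ...]]

    def exon(self, exon_id: str) -> Exon:
        for ex in self.exons:
            if ex.exon_id == exon_id:
                return ex
        raise UnknownSegmentError(f"unknown exon {exon_id!r}")

    @property
    def exon_order(self) -> dict[str, int]:
        return {ex.exon_id: i for i, ex in enumerate(self.exons)}

    @property
    def alternative_exons(self) -> tuple[str, ...]:
        return tuple(ex.exon_id for ex in self.exons if ex.kind == "alternative")

    def acceptor_runs(self) -> list[tuple[str, ...]]:
        """Contiguous runs of alternative-acceptor exons (each run = one choice)."""
        runs: list[tuple[str, ...]] = []
        current: list[str] = []
        for ex in self.exons:
            if ex.kind == "alternative_acceptor":
                current.append(ex.exon_id)
            elif current:
                runs.append(tuple(current))
                current = []
        if current:
            runs.append(tuple(current))
        return runs

    def without_exon(self, exon_id: str) -> "SpliceGraph":
        """Return a copy of the graph with one exon deleted (knockout model)."""
        if exon_id not in self.exon_order:
            raise UnknownSegmentError(f"unknown exon {exon_id!r}")
        exons = tuple(ex for ex in self.exons if ex.exon_id != exon_id)
        groups = {lbl: eid for lbl, eid in self.acceptor_groups.items() if eid != exon_id}
        segments = {
            lbl: tuple(e for e in eids if e != exon_id)
            for lbl, eids in self.segments.items()
        }
        segments = {lbl: eids for lbl, eids in segments.items() if eids}
        return SpliceGraph(self.gene_id, exons, groups, segments)


@dataclass(frozen=True)
class TranscriptIsoform:
    isoform_id: str
    exon_path: tuple[str, ...]
    segment_state: Mapping[str, str]


ANCHOR_CLASSES = ("transmembrane", "gpi_anchored", "acceptor25a_silenced")


@dataclass
class Proteoform:
    proteoform_id: str
    aa_sequence: str
    anchor_class: str
    segment_inclusion: dict[str, bool]
    translation_efficiency: float
    residue_exons: tuple[str, ...] = ()
    source_isoform: str | None = None

    @property
    def translated_exons(self) -> frozenset[str]:
        return frozenset(self.residue_exons)


@dataclass(frozen=True)
class GpiMotifRule:
    """Regular-motif rule for a GPI omega-site at a premature C-terminus.

    The omega residue (the final residue of the truncated proteoform) must be
    small, and the window of residues immediately upstream must be
    sufficiently hydrophobic.  This is a configurable motif rule, not a
    trained predictor.
    """

    small_residues: str = "GASNDC"
    hydrophobic_residues: str = "AVILMFWY"
    window: int = 6
    min_hydrophobic: int = 3

    def matches(self, aa_sequence: str) -> bool:
        if not aa_sequence:
            return False
        omega = aa_sequence[-1]
        if omega not in self.small_residues:
            return False
        upstream = aa_sequence[max(0, len(aa_sequence) - 1 - self.window) : -1]
        n_hydro = sum(1 for aa in upstream if aa in self.hydrophobic_residues)
        return n_hydro >= self.min_hydrophobic


DEFAULT_EFFICIENCY = {
    "transmembrane": 1.0,
    "gpi_anchored": 1.0,
    # acceptor-25a transcripts are translationally repressed; the default of
    # 0.0 encodes "below detection", matching the behaviour of the synthetic
    # generator for 25a-encoded peptides.
    "acceptor25a_silenced": 0.0,
}


def build_splice_graph(
    exon_table: Iterable[Mapping[str, str] | Exon],
    gene_id: str = "gene",
    segments: Mapping[str, Sequence[str]] | None = None,
) -> SpliceGraph:
    """Validate exon records and assemble a :class:`SpliceGraph`.

    Records carry ``exon_id``, ``sequence``, ``kind`` and an optional
    ``acceptor_label`` (required for kind ``alternative_acceptor``).
    """
    exons: list[Exon] = []
    seen: set[str] = set()
    acceptor_groups: dict[str, str] = {}
    for rec in exon_table:
        if not isinstance(rec, Exon):
            rec = Exon(
                exon_id=str(rec["exon_id"]),
                sequence=str(rec["sequence"]).upper(),
                kind=str(rec["kind"]),
                acceptor_label=(rec.get("acceptor_label") or None),
            )
        if rec.exon_id in seen:
            raise GraphStructureError(f"duplicate exon_id {rec.exon_id!r}")
        seen.add(rec.exon_id)
        if rec.kind not in EXON_KINDS:
            raise GraphStructureError(
                f"exon {rec.exon_id!r}: unknown kind {rec.kind!r}"
            )
        if not _DNA_RE.match(rec.sequence):
            raise SequenceFormatError(
                f"exon {rec.exon_id!r}: sequence is not uppercase DNA over ACGT"
            )
        if rec.kind == "alternative_acceptor":
            if not rec.acceptor_label:
                raise GraphStructureError(
                    f"exon {rec.exon_id!r}: alternative_acceptor needs a label"
                )
            if rec.acceptor_label in acceptor_groups:
                raise GraphStructureError(
                    f"duplicate acceptor label {rec.acceptor_label!r}"
                )
            acceptor_groups[rec.acceptor_label] = rec.exon_id
        exons.append(rec)

    seg_map: dict[str, tuple[str, ...]] = {}
    if segments:
        for label, eids in segments.items():
            for eid in eids:
                if eid not in seen:
                    raise GraphStructureError(
                        f"segment {label!r} names unknown exon {eid!r}"
                    )
            seg_map[label] = tuple(eids)
    return SpliceGraph(gene_id, tuple(exons), acceptor_groups, seg_map)


def read_exon_table(path: str | Path) -> list[Exon]:
    """Read exon records from a CSV with columns exon_id, kind, acceptor_label, sequence."""
    exons: list[Exon] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            exons.append(
                Exon(
                    exon_id=row["exon_id"],
                    sequence=row["sequence"].upper(),
                    kind=row["kind"],
                    acceptor_label=row.get("acceptor_label") or None,
                )
            )
    return exons


def enumerate_isoforms(
    graph: SpliceGraph,
    segment_choices: Mapping[str, object] | None = None,
) -> list[TranscriptIsoform]:
    """Enumerate every legal transcript isoform of the graph.

    Each cassette (``alternative``) exon contributes an in/out binary choice
    and each contiguous acceptor run contributes one choice among its
    members.  ``segment_choices`` constrains the enumeration: keys are
    alternative exon ids (value truthy = included, falsy = skipped) or
    acceptor labels (value truthy = that acceptor must be used).  Output is
    deterministically ordered by exon-path lexicographic order.
    """
    constraints = dict(segment_choices or {})
    alt_exons = list(graph.alternative_exons)
    runs = graph.acceptor_runs()

    known = set(alt_exons) | set(graph.acceptor_groups)
    for key in constraints:
        if key not in known:
            raise UnknownSegmentError(
                f"constraint names unknown segment/exon {key!r}"
            )

    label_by_exon = {eid: lbl for lbl, eid in graph.acceptor_groups.items()}

    alt_options: list[list[tuple[str, bool]]] = []
    for eid in alt_exons:
        if eid in constraints:
            alt_options.append([(eid, bool(constraints[eid]))])
        else:
            alt_options.append([(eid, True), (eid, False)])

    run_options: list[list[str]] = []
    for run in runs:
        forced = [eid for eid in run if constraints.get(label_by_exon.get(eid, ""), False)]
        run_options.append(forced if forced else list(run))

    isoforms: list[TranscriptIsoform] = []
    for alt_choice in itertools.product(*alt_options):
        included = {eid for eid, inc in alt_choice if inc}
        for acceptors in itertools.product(*run_options):
            chosen = set(acceptors)
            path = tuple(
                ex.exon_id
                for ex in graph.exons
                if ex.kind == "constitutive"
                or (ex.kind == "alternative" and ex.exon_id in included)
                or (ex.kind == "alternative_acceptor" and ex.exon_id in chosen)
            )
            state: dict[str, str] = {}
            for seg, eids in graph.segments.items():
                seg_alts = [e for e in eids if e in set(alt_exons)]
                if seg_alts:
                    state[seg] = (
                        "included" if any(e in included for e in seg_alts) else "skipped"
                    )
            for eid in acceptors:
                state[label_by_exon[eid]] = "chosen"
            isoforms.append(
                TranscriptIsoform(
                    isoform_id=f"{graph.gene_id}/" + "-".join(path),
                    exon_path=path,
                    segment_state=state,
                )
            )
    isoforms.sort(key=lambda iso: iso.exon_path)
    return isoforms


def translate_isoform(
    isoform: TranscriptIsoform,
    graph: SpliceGraph,
    frame_offset: int = 0,
    gpi_rule: GpiMotifRule | None = None,
    efficiency_table: Mapping[str, float] | None = None,
    silencing_acceptors: frozenset[str] = frozenset({"25a"}),
) -> Proteoform:
    """Translate a transcript isoform into a classified proteoform.

    Translation starts at ``frame_offset`` within the concatenated exon
    sequence and halts at the first in-frame stop.  Anchor class:

    * ``gpi_anchored`` -- the stop lies within a cassette (alternative) exon
      and the resulting C-terminus matches the GPI omega-site motif rule;
    * ``acceptor25a_silenced`` -- the transcript uses a silencing acceptor
      (default ``25a``) without a premature stop in a cassette exon;
    * ``transmembrane`` -- otherwise (the full-length canonical form).
    """
    gpi_rule = gpi_rule or GpiMotifRule()
    efficiency = dict(DEFAULT_EFFICIENCY)
    if efficiency_table:
        efficiency.update(efficiency_table)

    cds_parts = []
    nt_exons: list[str] = []
    for eid in isoform.exon_path:
        ex = graph.exon(eid)
        cds_parts.append(ex.sequence)
        nt_exons.extend([eid] * len(ex.sequence))
    cds = "".join(cds_parts)[frame_offset:]
    nt_exons = nt_exons[frame_offset:]
    if len(cds) < 3:
        raise TranslationError(
            f"{isoform.isoform_id}: no reading possible (CDS shorter than one codon)"
        )

    aa: list[str] = []
    residue_exons: list[str] = []
    stop_exon: str | None = None
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in _STOP_CODONS:
            stop_exon = nt_exons[i]
            break
        aa.append(_CODON_TABLE[codon])
        residue_exons.append(nt_exons[i])
    if not aa:
        raise TranslationError(f"{isoform.isoform_id}: empty translation")
    aa_sequence = "".join(aa)

    alt_set = set(graph.alternative_exons)
    premature = stop_exon is not None and stop_exon in alt_set
    chosen_acceptors = {
        lbl for lbl, eid in graph.acceptor_groups.items() if eid in isoform.exon_path
    }
    if premature and gpi_rule.matches(aa_sequence):
        anchor = "gpi_anchored"
    elif not premature and chosen_acceptors & silencing_acceptors:
        anchor = "acceptor25a_silenced"
    else:
        anchor = "transmembrane"

    translated = set(residue_exons)
    inclusion: dict[str, bool] = {}
    for seg, eids in graph.segments.items():
        seg_alts = [e for e in eids if e in alt_set]
        if seg_alts:
            inclusion[seg] = any(e in translated for e in seg_alts)
    for lbl, eid in graph.acceptor_groups.items():
        inclusion[lbl] = eid in translated

    return Proteoform(
        proteoform_id=f"{isoform.isoform_id}:pf",
        aa_sequence=aa_sequence,
        anchor_class=anchor,
        segment_inclusion=inclusion,
        translation_efficiency=float(efficiency[anchor]),
        residue_exons=tuple(residue_exons),
        source_isoform=isoform.isoform_id,
    )


def _normalize_junction(key) -> tuple[str, str]:
    if isinstance(key, tuple):
        return (str(key[0]), str(key[1]))
    parts = str(key).replace("->", "-").split("-")
    if len(parts) != 2:
        raise UnknownSegmentError(f"cannot parse junction key {key!r}")
    return (parts[0], parts[1])


def junction_psi(
    graph: SpliceGraph,
    junction_read_counts: Mapping[object, float],
    target: str,
) -> float:
    """Percent-spliced-in of one alternative exon from junction read counts.

    ``target`` is an alternative exon id, or a segment label governing
    exactly one alternative exon.  Junctions touching the exon support
    inclusion; junctions connecting an upstream to a downstream exon (thereby
    skipping it) support exclusion.  Each side is averaged over its
    informative junctions with equal weight and PSI is
    ``mean(inclusion) / (mean(inclusion) + mean(exclusion))``.
    """
    alt_set = set(graph.alternative_exons)
    exon_id = target
    if target not in alt_set:
        seg_alts = [e for e in graph.segments.get(target, ()) if e in alt_set]
        if len(seg_alts) != 1:
            raise UnknownSegmentError(
                f"{target!r} is neither an alternative exon nor a segment with "
                "exactly one alternative exon"
            )
        exon_id = seg_alts[0]

    order = graph.exon_order
    pos = order[exon_id]
    inclusion: list[float] = []
    exclusion: list[float] = []
    for key, count in junction_read_counts.items():
        count = float(count)
        if count < 0:
            raise ValueError("junction read counts must be non-negative")
        a, b = _normalize_junction(key)
        if a not in order or b not in order:
            continue
        if exon_id in (a, b):
            inclusion.append(count)
        elif order[a] < pos < order[b]:
            exclusion.append(count)
    if not inclusion and not exclusion:
        raise UndefinedRatioError(f"no informative junctions for {target!r}")
    inc = sum(inclusion) / len(inclusion) if inclusion else 0.0
    exc = sum(exclusion) / len(exclusion) if exclusion else 0.0
    if inc + exc == 0:
        raise UndefinedRatioError(f"all informative junction counts are zero for {target!r}")
    return inc / (inc + exc)


def proteoforms_to_fasta(proteoforms: Iterable[Proteoform], path: str | Path) -> None:
    """Export proteoforms as FASTA; headers carry class and inclusion flags."""
    records = []
    for pf in proteoforms:
        flags = ",".join(
            f"{lbl}={'1' if inc else '0'}"
            for lbl, inc in sorted(pf.segment_inclusion.items())
        )
        desc = f"anchor={pf.anchor_class} efficiency={pf.translation_efficiency:g} {flags}"
        records.append(SeqRecord(Seq(pf.aa_sequence), id=pf.proteoform_id, description=desc))
    SeqIO.write(records, str(path), "fasta")
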