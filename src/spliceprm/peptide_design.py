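"""In-silico tryptic digestion, splice-specificity classing, and PRM assay design.

Digestion uses full tryptic specificity: cleavage after K or R unless the
next residue is proline.  Peptides are classified against the enumerated
proteoforms of a gene: *constitutive* peptides occur in every proteoform,
*proteoform-specific* peptides discriminate exactly one segment state (and
are absent from the background proteome), everything else is *shared_subset*.
Junction-spanning peptides need no special casing because digestion operates
on full proteoform sequences.

Monoisotopic masses come from pyteomics; carbamidomethylation of cysteine is
the fixed modification convention, and heavy reference channels are modelled
as C-terminal Lys8/Arg10 labels (peptides without a C-terminal K/R cannot
carry a heavy channel).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass
from Bio import SeqIO

from .errors import (
    AssayDesignError,
    SequenceFormatError,
    UnknownModificationError,
)
from .splice_model import Proteoform

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

PROTON_MASS = 1.00727646688

#: Monoisotopic mass deltas (Da) of supported modifications.
MODIFICATION_MASSES = {
    "carbamidomethyl": 57.021464,  # fixed on C
    "lys8": 8.014199,              # 13C6 15N2 heavy lysine
    "arg10": 10.008269,            # 13C6 15N4 heavy arginine
}

DEFAULT_OBSERVABLE_BOUNDS = (7, 30)


@dataclass
class PeptideRecord:
    sequence: str
    missed_cleavages: int
    start: int = 0
    parent_proteoforms: frozenset[str] = frozenset()
    specificity: str | None = None
    segment_tag: str | None = None
    monoisotopic_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.monoisotopic_mass == 0.0:
            self.monoisotopic_mass = peptide_mass(self.sequence)


@dataclass(frozen=True)
class Fragment:
    ion: str
    mz: float
    intensity: float


@dataclass
class TransitionSet:
    peptide: str
    precursor_charge: int
    fragments: tuple[Fragment, ...]
    selected: tuple[Fragment, ...]


def _validate_aa(sequence: str) -> None:
    bad = set(sequence) - AA_ALPHABET
    if bad:
        raise SequenceFormatError(
            f"unknown residue(s) {sorted(bad)} in {sequence[:20]!r}..."
        )


def cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cleaves (K/R not followed by P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    aa_sequence: str,
    max_missed_cleavages: int = 0,
    length_bounds: tuple[int, int | None] = (1, None),
) -> list[PeptideRecord]:
    """Fully tryptic peptides of a protein, ordered by position then missed cleavages."""
    if not aa_sequence:
        return []
    _validate_aa(aa_sequence)
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    lo, hi = length_bounds
    sites = cleavage_sites(aa_sequence)
    bounds = [0] + sites + [len(aa_sequence)]
    fragments = [
        (bounds[i], aa_sequence[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]
    peptides: list[PeptideRecord] = []
    for i in range(len(fragments)):
        for mc in range(max_missed_cleavages + 1):
            if i + mc >= len(fragments):
                break
            seq = "".join(frag for _, frag in fragments[i : i + mc + 1])
            if len(seq) < lo or (hi is not None and len(seq) > hi):
                continue
            peptides.append(
                PeptideRecord(sequence=seq, missed_cleavages=mc, start=fragments[i][0])
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def count_observable_peptides(
    aa_sequence: str,
    observable_length_bounds: tuple[int, int] = DEFAULT_OBSERVABLE_BOUNDS,
) -> int:
    """Number of distinct fully tryptic 0-missed-cleavage peptides within bounds.

    This is the iBAQ denominator; the default 7-30 residue window is the
    common iBAQ convention.
    """
    peps = digest(aa_sequence, 0, observable_length_bounds)
    return len({p.sequence for p in peps})


def _load_background(background) -> list[str]:
    if background is None:
        return []
    if isinstance(background, (str, Path)):
        return [str(rec.seq) for rec in SeqIO.parse(str(background), "fasta")]
    seqs = []
    for item in background:
        seqs.append(item[1] if isinstance(item, tuple) else str(item))
    return seqs


def assign_specificity(
    peptides: Iterable[PeptideRecord],
    proteoforms: Sequence[Proteoform],
    background_proteome=None,
    acceptor_labels: frozenset[str] = frozenset(),
) -> list[PeptideRecord]:
    """Annotate peptides with parent sets, specificity class and segment tag.

    A peptide is *constitutive* when present in every proteoform of the gene;
    *proteoform_specific* when its parent set coincides with the set of
    proteoforms sharing one segment state (included or skipped) and the
    peptide is absent from the background proteome; *shared_subset*
    otherwise.  Tags are the acceptor label itself for acceptor states and
    ``segment+``/``segment-`` for cassette states.
    """
    bg = _load_background(background_proteome)
    all_ids = frozenset(pf.proteoform_id for pf in proteoforms)

    flags: set[str] = set()
    for pf in proteoforms:
        flags.update(pf.segment_inclusion)
    state_sets: dict[str, frozenset[str]] = {}
    for flag in flags:
        state_sets[flag] = frozenset(
            pf.proteoform_id for pf in proteoforms if pf.segment_inclusion.get(flag)
        )

    out: list[PeptideRecord] = []
    for pep in peptides:
        parents = frozenset(
            pf.proteoform_id for pf in proteoforms if pep.sequence in pf.aa_sequence
        )
        in_background = any(pep.sequence in seq for seq in bg)
        pep.parent_proteoforms = parents
        pep.specificity = "shared_subset"
        pep.segment_tag = None
        if parents == all_ids and parents:
            pep.specificity = "constitutive"
        elif parents and not in_background:
            for flag in sorted(state_sets):
                s = state_sets[flag]
                if not s or s == all_ids:
                    continue
                if parents == s:
                    pep.specificity = "proteoform_specific"
                    pep.segment_tag = flag if flag in acceptor_labels else f"{flag}+"
                    break
                if parents == all_ids - s:
                    pep.specificity = "proteoform_specific"
                    pep.segment_tag = (
                        f"{flag}-" if flag not in acceptor_labels else f"not_{flag}"
                    )
                    break
        out.append(pep)
    return out


_ION_RE = re.compile(r"^([abcxyz])(\d+)")


def _ion_sort_key(frag: Fragment) -> tuple[int, int]:
    m = _ION_RE.match(frag.ion)
    if not m:
        return (2, 0)
    series, idx = m.group(1), int(m.group(2))
    return (0 if series == "b" else 1 if series == "y" else 2, idx)


def select_transitions(
    peptide: str,
    fragments: Iterable[Fragment | tuple],
    n: int = 6,
    precursor_charge: int = 2,
) -> TransitionSet:
    """Pick the best ``n`` transitions by library intensity.

    Ties at the selection boundary are broken deterministically: b-series
    before y-series, then ascending fragment index.  The result is invariant
    under permutation of the input fragment list.
    """
    frags = tuple(
        f if isinstance(f, Fragment) else Fragment(*f) for f in fragments
    )
    if not frags:
        raise AssayDesignError(f"no fragments supplied for {peptide!r}")
    ranked = sorted(frags, key=lambda f: (-f.intensity, *_ion_sort_key(f)))
    return TransitionSet(
        peptide=peptide,
        precursor_charge=precursor_charge,
        fragments=frags,
        selected=tuple(ranked[: min(n, len(ranked))]),
    )


def peptide_mass(
    sequence: str,
    modifications: Sequence[str] = ("carbamidomethyl",),
    heavy: bool = False,
) -> float:
    """Monoisotopic peptide mass in Da.

    ``modifications`` names entries of :data:`MODIFICATION_MASSES`;
    ``carbamidomethyl`` applies per cysteine.  With ``heavy=True`` the
    C-terminal K/R carries a Lys8/Arg10 label (raises if the peptide has no
    C-terminal K/R and therefore cannot carry a heavy channel).
    """
    _validate_aa(sequence)
    m = _pmass.calculate_mass(sequence=sequence, monoisotopic=True)
    for mod in modifications:
        if mod not in MODIFICATION_MASSES:
            raise UnknownModificationError(f"unknown modification {mod!r}")
        if mod == "carbamidomethyl":
            m += MODIFICATION_MASSES[mod] * sequence.count("C")
        elif mod in ("lys8", "arg10"):
            m += MODIFICATION_MASSES[mod]
    if heavy:
        delta = heavy_label_delta(sequence)
        if delta is None:
            raise UnknownModificationError(
                f"{sequence!r} has no C-terminal K/R and cannot carry a heavy label"
            )
        m += delta
    return m


def heavy_label_delta(sequence: str) -> float | None:
    """Mass delta of the heavy reference channel, or None if not labelable."""
    if sequence.endswith("K"):
        return MODIFICATION_MASSES["lys8"]
    if sequence.endswith("R"):
        return MODIFICATION_MASSES["arg10"]
    return None


def precursor_mz(mass: float, charge: int) -> float:
    """m/z of a precursor of given monoisotopic mass and charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON_MASS) / charge
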