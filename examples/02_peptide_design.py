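"""Design splice-isoform-specific proteotypic peptides for the example gene.

Digests every proteoform (full tryptic rule: after K/R unless before P),
classifies peptides as constitutive / proteoform-specific / shared, and ranks
spectral-library fragments into a 6-transition PRM assay.
Run: python examples/02_peptide_design.py
"""

from spliceprm import assign_specificity, digest, peptide_mass, precursor_mz, select_transitions
from spliceprm.gene_models import ACCEPTOR_LABELS, as5_proteoforms
from spliceprm.peptide_design import Fragment, heavy_label_delta

proteoforms = as5_proteoforms()
seen = {}
for pf in proteoforms:
    for pep in digest(pf.aa_sequence, 0, (6, 25)):
        seen.setdefault(pep.sequence, pep)
peptides = assign_specificity(
    list(seen.values()), proteoforms, acceptor_labels=ACCEPTOR_LABELS
)

print("peptide              specificity            tag    mass (Da)  m/z 2+   heavy")
for pep in sorted(peptides, key=lambda p: p.sequence):
    mz = precursor_mz(pep.monoisotopic_mass, 2)
    labelable = heavy_label_delta(pep.sequence) is not None
    print(
        f"{pep.sequence:20s} {pep.specificity:22s} {str(pep.segment_tag):6s} "
        f"{pep.monoisotopic_mass:9.4f} {mz:8.3f}  {'K/R' if labelable else 'no'}"
    )

print(
    "\nConstitutive peptides occur in every proteoform and serve as the"
    "\nreference; junction peptides (e.g. the e23|e24 spanning one) uniquely"
    "\nreport one splice state.  Peptides without C-terminal K/R cannot carry"
    "\na heavy SpikeTides label and are excluded from the assay."
)

# rank a mock spectral-library entry into the best 6 transitions
frags = [Fragment(f"y{i}", 300.0 + 50 * i, inten)
         for i, inten in enumerate([55, 10, 80, 95, 40, 70, 20, 65], start=3)]
ts = select_transitions("LNPADTVGSEYK", frags, n=6)
print("\ntop-6 transitions for LNPADTVGSEYK (by library intensity):")
for rank, f in enumerate(ts.selected, 1):
    print(f"  {rank}. {f.ion:4s} m/z {f.mz:7.1f}  intensity {f.intensity:g}")

light = peptide_mass("LNPADTVGSEYK")
heavy = peptide_mass("LNPADTVGSEYK", heavy=True)
print(f"\nlight/heavy precursor mass shift: {heavy - light:.4f} Da (Lys8 label)")
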