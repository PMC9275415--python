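# spliceprm

Proteoform-centric quantification of alternative splicing by targeted mass
spectrometry, built around the biology of the neurexin-3 AS5 segment: a
cassette exon carrying a premature stop codon that converts the transmembrane
adhesion molecule into a short GPI-anchored proteoform, and a trio of
alternative acceptor sites (25a/25b/25c) of which 25a marks translationally
silenced mRNAs.

The package is a library with five building blocks:

- **`splice_model`** — splice-graph representation of a gene (exons carry
  their own sequences, no genomic coordinates), combinatorial isoform
  enumeration, translation into classified proteoforms (transmembrane /
  GPI-anchored via a configurable ω-site motif rule / acceptor-25a silenced),
  and junction-read PSI.
- **`peptide_design`** — in-silico tryptic digestion (cleavage after K/R
  unless before P), splice-specificity classing of peptides against the
  enumerated proteoforms and a background proteome, observable-peptide counts
  for iBAQ, top-6 transition selection from a spectral library, and
  monoisotopic masses (fixed carbamidomethyl-C, heavy C-terminal Lys8/Arg10
  reference labels).
- **`prm_quant`** — parallel-reaction-monitoring quantification: transition
  integration, light/heavy ratios against the 2 fmol/µg heavy spike, TIC
  normalization, log₂ control-relative centering, per-protein medians,
  percent change with SEM, and splice-site inclusion % calibrated against
  recombinant 100 %-inclusion standards:

  `I = 100 · (R_spec/R_const)_sample / (R_spec/R_const)_standard`

- **`shotgun_diff`** — IP-MS differential enrichment: kNN imputation, protein
  roll-up, iBAQ, an empirical-Bayes moderated t-test (per-protein variances
  shrunk toward a scaled-F moment-matched prior; verified against the
  R/Bioconductor implementation), BH / two-stage BKY step-up correction, and
  the strict fold-change > 2.0, q < 0.05 interactor screen.
- **`synthetic_data`** — a ground-truth generator for both data types
  (lognormal transition/peptide/sample noise, hard detection censoring,
  genotype presets for wild type, HA-knockin, and the exon-24 knockout)
  so every stage is testable without any external download.

A thin `spliceprm` command line (`simulate`, `design`, `quantify`,
`inclusion`, `diff`) wraps the library for shell use; `examples/` contains
one narrative script per capability.

## Worked example

```bash
python examples/03_prm_quantification.py
```

simulates a 5-vs-5 wild-type vs exon-24-knockout PRM experiment and runs the
full quantification chain on constitutive peptides (present in every
proteoform, so they report total gene-level protein):

```
ground truth (fmol/ug):
  wild type: {'gpi': 2.7, 'tm_25b': 0.65, 'tm_25c': 0.65, 'silenced_25a': 0.0}
  knockout : {'gpi': 0.0, 'tm_25b': 0.78, 'tm_25c': 0.78, 'silenced_25a': 0.0}
  true total-protein reduction: 61.0%
...
estimated reduction: 61.9 +/- 0.7 % (SEM, 5v5)
```

Losing the GPI proteoform while mildly up-regulating the transmembrane forms
reduces total protein by about 61 %, and the pipeline recovers it from noisy
transition areas.  `examples/04_inclusion_calibration.py` shows the
recombinant-calibrated inclusion estimates tracking known standard mixtures
(0/25/50/75/100 %), and `examples/05_ipms_enrichment.py` recovers three
planted interactors from 500 background proteins with no false positives.

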