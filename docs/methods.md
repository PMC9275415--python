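# Methods

This note documents the models, numerical conventions and design choices
behind `spliceprm`, and what the synthetic generator does and does not
emulate.

## Splice model

A gene is an ordered list of exons, each carrying its own nucleotide
sequence and one of three kinds: constitutive, cassette (`alternative`), or
`alternative_acceptor`. Contiguous runs of acceptor exons are mutually
exclusive alternatives. Genomic coordinates are deliberately not modelled:
nothing in the downstream quantification needs them, and their absence keeps
the model genome-build-free.

Isoform enumeration is the full combinatorial product: each cassette exon
contributes an in/out choice and each acceptor run one choice among its
members, so a graph with *k* cassette exons and acceptor runs of sizes
*g₁…gₘ* yields `2^k · Π gⱼ` isoforms, deterministically ordered by exon-path
lexicographic order. Translation proceeds codon by codon from a frame offset
and halts at the first in-frame stop, recording the source exon of every
residue (this provenance is what later lets peptides be attributed to splice
states without special-casing junctions).

Proteoform classes:

- **gpi_anchored** — the stop lies inside a cassette exon and the C-terminus
  matches a GPI ω-site motif rule. The rule is a configurable regular motif,
  not a trained predictor: the ω residue (the new C-terminus) must be small
  (default set `GASNDC`) and the preceding window (default 6 residues) must
  contain at least 3 hydrophobic residues (`AVILMFWY`). The exact ω position
  within the cassette exon is not fixed by the underlying biology available
  to us, which is why the rule is configurable rather than hard-coded.
- **acceptor25a_silenced** — the transcript splices into a silencing acceptor
  (default `25a`) without a premature cassette stop. Silencing is represented
  as a class label plus a scalar translation efficiency used only by the
  synthetic generator; the default efficiency is 0.0, i.e. below detection,
  because that is the regime the quantification must handle (specific
  peptides present in the transcriptome but absent from the proteome).
- **transmembrane** — everything else (the canonical full-length form).

Junction PSI from read counts uses equal-weight averaging on each side:
`PSI = mean(inclusion-junction counts) / (mean(inclusion) + mean(exclusion))`,
where junctions touching the cassette exon support inclusion and junctions
connecting an upstream to a downstream exon support exclusion. The averaging
rule is stated explicitly because junction sets differ in size between the
two sides.

## Peptide design

Digestion applies full tryptic specificity — cleavage after K or R unless
followed by P — with configurable missed cleavages and length bounds.
Specificity classes are defined over the enumerated proteoforms of the gene:

- *constitutive*: present in every proteoform (these are the reference
  peptides; they must lie upstream of the cassette exon to survive the GPI
  truncation);
- *proteoform_specific*: the peptide's parent set coincides exactly with the
  set of proteoforms sharing one segment state (included or skipped, or one
  acceptor choice) and the peptide occurs nowhere in the background proteome;
- *shared_subset*: everything else.

Because digestion runs on full proteoform sequences, junction-spanning
peptides arise naturally and are tagged by the state they discriminate.
Enlarging the background proteome can only demote a peptide's class, never
promote it (tested property).

The iBAQ denominator counts distinct fully tryptic 0-missed-cleavage
peptides of length 7–30 (the common iBAQ convention; configurable). Heavy
reference channels are modelled as C-terminal Lys8 (+8.0142 Da) / Arg10
(+10.0083 Da) labels, matching synthetic SpikeTides chemistry; peptides
without a C-terminal K/R cannot carry a heavy channel and are flagged.
Transition selection takes the top 6 library fragments by intensity with a
deterministic tie-break (b-series before y, then ascending index), making the
selection invariant under permutation of the library entry.

## PRM quantification

Order of operations: integrate selected transitions per
sample/peptide/channel → light/heavy ratio → log₂ → control-relative
centering (per-peptide mean of the control condition) → median per protein
per sample (median taken on the log scale; an even peptide count reports the
geometric midpoint).

TIC normalization (each sample divided by its summed 2+–5+ precursor
intensity relative to the geometric mean of all samples) is computed and
logged, and normalized areas are reported per channel — but the light/heavy
ratio is formed from the raw integrated areas. The per-sample TIC factor
divides both channels identically, so it cancels exactly inside the ratio;
forming the ratio before any per-sample division keeps that cancellation
exact in floating point as well. This makes two invariances hold exactly:
jointly scaling one sample's areas and TIC leaves every downstream ratio
unchanged (injection-scale equivariance), and scaling one peptide's light and
heavy areas together leaves its ratio unchanged (heavy-standard invariance).
Normalizing *ratios* by the TIC factor instead would break the first
invariance, because rescaling one sample moves the geometric-mean reference
of every sample.

Detection gating: a peptide/sample is quantifiable when its light channel has
at least `min_transitions` (default 3 of 6) non-zero transition areas.
Not-detected peptides are excluded from protein medians but enter inclusion
estimates as 0 % with a `not_detected` provenance — this is the behaviour
required by translationally silenced segments whose peptides are real but
absent from tissue.

With the heavy reference spiked at 2 fmol per µg of total endogenous peptide,
a light/heavy ratio converts to an absolute amount as `ratio × 2 fmol/µg`.

**Percent change** between conditions is `100·(1 − mean_case/mean_control)`
over replicate-level protein summaries (linear control-relative ratios), with
the SEM propagated across both groups by the delta method. With a single
replicate the point estimate is returned and the SEM is undefined. Note the
small-sample caveat: with 5 vs 5 replicates an interval of ±2·SEM has
nominal coverage P(|t₈| ≤ 2) ≈ 92 %, not 95 %; users wanting exact 95 %
intervals should multiply the SEM by t₀.₉₇₅,₈ ≈ 2.31.

**Inclusion percent** calibrates the specific/constitutive ratio against a
recombinant standard measured with the same assay:
`I = 100 · (R_spec/R_const)_sample / (R_spec/R_const)_standard`, with
geometric means over the peptides of each class and the median over
calibration replicates. The double ratio cancels peptide-specific response
and recovery factors — this is the scientific reason for the recombinant
calibration, and the synthetic generator reproduces it (see below). Values
may exceed 100 % from noise and are reported uncapped, with a warning above
a configurable bound (default 150 %).

## IP-MS differential enrichment

Missing peptide intensities are imputed from the k (default 10) nearest
peptide rows by Euclidean distance over co-observed log₂ intensities,
distance-weighted; fully missing rows are dropped with a warning and k is
clipped to the available rows. Imputation precedes protein roll-up
(summation over peptides), which precedes iBAQ. No between-sample
normalization is applied by default: in affinity-purification designs the
negative-control precipitates genuinely carry little material, and equalizing
totals would destroy the contrast (normalization is opt-in).

The moderated t-test shrinks per-protein pooled variances s² (df d) toward a
prior s₀² with weight d₀, where (d₀, s₀²) are estimated by matching the first
two moments of log s² to a scaled F distribution (digamma/trigamma moment
equations, trigamma inverted by Newton iteration). The moderated statistic is
t = log₂FC / √(s²_post·(1/n₁+1/n₂)) with s²_post = (d₀s₀² + d s²)/(d₀+d) and
p-values from a t distribution on d+d₀ df. Setting the prior df to 0 recovers
the ordinary pooled t-test exactly; the full estimator reproduces the
R/Bioconductor reference implementation to 10⁻¹⁰ on a frozen fixture. One
consequence of the moment estimator worth noting: because E[log s²] under
chi-square sampling is biased below log σ², a degenerate dataset in which all
observed s² are identical yields a common prior slightly *above* the shared
s² (factor `exp(log(d/2) − ψ(d/2))`), onto which all posterior variances
collapse.

Multiplicity is controlled with Benjamini–Hochberg (default) or the two-stage
Benjamini–Krieger–Yekutieli step-up. The interactor screen is strict:
linear fold change > 2.0 AND q < 0.05, sorted by q then fold change.
When proteoform-resolved output is requested, a specificity filter restricts
the roll-up to proteoform-specific and constitutive peptide signals.

## Synthetic data generator

The generator emulates integrated transition/peptide areas, not raw spectra.
Structure of one PRM measurement:

```
light area = abundance(fmol/µg) · response/fmol · recovery_peptide · r_sample · frac_transition · LN(cv_t)
heavy area = 2 fmol/µg          · response/fmol ·                    r_sample · frac_transition · LN(cv_t)
TIC        = base · r_sample
```

- `r_sample` ~ lognormal (CV 0.10) is the per-sample injection/response
  scale; it multiplies every area and the TIC, and cancels in light/heavy
  ratios (this is what the TIC-equivariance property exercises).
- `recovery_peptide` ~ lognormal (CV 0.15) is a per-peptide recovery bias of
  the endogenous channel relative to the heavy reference (the heavy peptide
  is spiked after digestion). It is frozen with the assay — constant across
  samples, conditions and calibration runs — because it models peptide
  chemistry, not run-to-run noise. Control-relative centering and
  recombinant calibration cancel it exactly; this is precisely why those
  steps exist in the real workflow.
- transition-level noise is multiplicative lognormal (CV 0.10) per transition
  and channel; transition areas partition the peptide area by the library
  fragment proportions (Dirichlet-distributed, frozen with the assay).
- below-detection is a hard censoring threshold on the light area applied
  after noise (default 5·10³ area units against a response of 10⁶ per
  fmol/µg), which produces the "specific peptide not detectable" regime.

All CVs are assumptions, not measured values; they were chosen once as
plausible for a well-optimized targeted assay and are configurable.

Genotype presets (fmol/µg): wild type — GPI 2.70, transmembrane 25b 0.65,
25c 0.65, 25a-silenced 0.0; exon-24 knockout — GPI 0.0, transmembrane ×1.2.
These values encode the study conditions the pipeline must resolve: the
knockout loses the GPI proteoform entirely, mildly up-regulates the
canonical forms, and reduces total gene-level protein by 61 %. The
recombinant standards are pure single proteoforms at 2 fmol/µg (fully
translated, so silenced-in-vivo peptides are detectable there), and mixture
standards combine an inclusion-positive and an inclusion-negative proteoform
at a known molar fraction.

The IP-MS generator draws background proteins over three orders of magnitude
of abundance with 1–5 peptides each (peptide-level lognormal noise, CV 0.20),
scales the truly enriched proteins (defaults: three interactors at folds 8,
16 and 32, matching a strong IP) in the case group, and injects missing
values at a configured rate (default 0.15) with probability decreasing
logistically in log-intensity; every peptide keeps its largest observation.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: chromatographic interference and peak-integration
errors, retention-time drift, correlated (batch) noise across samples,
between-animal biological variance, missed-cleavage and modification
heterogeneity, compositional effects between proteins, and not-at-random
censoring of the heavy channel. In particular, the absence of biological
variance makes replicate scatter purely technical, so real-data SEMs will be
larger than the simulated ones.

## Problem sizes and numerical conventions

Simulation-based checks use the study's replicate structure (5 vs 5), a
500-protein IP background, 200-run recovery ensembles, a 5-point inclusion
grid over up to 200 seeds, and 5,000-protein null matrices for test
calibration — sizes chosen so the full suite and the acceptance script each
run in minutes on one core. Log base 2 is used throughout, with linear
back-transforms for reporting. All randomness flows from a single seed;
per-stage substreams are derived with CRC-32 of the stage name (a plain
character-sum was rejected after it produced colliding, correlated
substreams). Ties in transition selection and medians are resolved
deterministically; every simulated dataset is byte-reproducible from
(config, seed).

## Known limitations

- The splice model covers cassette exons and alternative acceptor runs; it
  does not model alternative donors, intron retention or NMD (the biology at
  hand does not need them).
- The GPI motif rule is a heuristic; it classifies, it does not predict.
- Inclusion estimates assume the recombinant standard shares the assay's
  peptide response and recovery factors; a degraded standard would bias all
  inclusion values multiplicatively.
- The moderated test assumes approximate normality of log intensities and
  exchangeable variances; heavy-tailed contamination is not modelled.
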