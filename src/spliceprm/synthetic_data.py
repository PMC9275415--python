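"""Synthetic PRM and IP-MS data with known ground truth.

The generator emulates the measurement process of heavy-reference PRM and of
affinity-purification shotgun MS at the level this pipeline consumes
(integrated transition areas / peptide peak areas), with:

* a per-sample response factor (injection/instrument scale, lognormal,
  CV ``cv_sample``) multiplying every area and the sample TIC,
* a per-peptide recovery factor (lognormal, CV ``cv_peptide``) frozen with
  the assay: it models peptide-specific digestion/recovery bias of the
  endogenous (light) channel relative to the heavy reference, is constant
  across samples and calibration runs, and is exactly what control-relative
  centering and recombinant calibration are designed to cancel,
* multiplicative lognormal noise per transition (CV ``cv_transition``),
* a hard detection threshold on areas applied after noise (below-detection
  censoring; this produces the "not detectable" behaviour of
  translationally silenced 25a peptides),
* the fixed heavy spike of 2 fmol per ug of total endogenous peptide.

Genotype presets are parameterized so that the delta-Ex24 knockout loses the
GPI-anchored proteoform entirely, mildly up-regulates the canonical
transmembrane proteoforms (factor 1.2), and reduces total gene-level protein
by 61%.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gene_models
from .errors import ConfigurationError, UnknownSegmentError
from .peptide_design import (
    PeptideRecord,
    assign_specificity,
    digest,
    heavy_label_delta,
    peptide_mass,
    precursor_mz,
)

BASE_RESPONSE_PER_FMOL = 1.0e6   # arbitrary area units per fmol/ug
BASE_TIC = 1.0e9
DETECTION_LIMIT_AREA = 5.0e3

#: Wild-type proteoform abundances (fmol per ug total peptide).  The GPI:TM
#: split and the knockout's 1.2x transmembrane elevation together give the
#: 61% total-protein reduction of the knockout preset.
WILDTYPE_ABUNDANCE = {
    "gpi": 2.70,
    "tm_25b": 0.65,
    "tm_25c": 0.65,
    "silenced_25a": 0.0,   # 25a transcripts are translationally silenced
}
TM_UPREGULATION = 1.2

#: Truly enriched IP interactors of the HA-tagged proteoform (fold changes).
DEFAULT_IP_ENRICHED = {"FAM19A1": 8.0, "NXPH1": 16.0, "FAM19A2": 32.0}

PRESETS = ("wildtype", "as5_ha", "delta_ex24", "recombinant_standard")


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = _cv_to_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class GroundTruth:
    """Fully serialized ground truth; (config, seed) reproduces any dataset."""

    name: str
    proteoform_fmol_per_ug: dict[str, float]
    inclusion_truth: dict[str, float] = field(default_factory=dict)
    ip_enriched: dict[str, float] = field(default_factory=dict)
    cv_transition: float = 0.10
    cv_peptide: float = 0.15
    cv_sample: float = 0.10
    ip_cv: float = 0.20
    ip_missing_rate: float = 0.15
    heavy_spike_fmol_per_ug: float = 2.0
    detection_limit_area: float = DETECTION_LIMIT_AREA

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.proteoform_fmol_per_ug.values()):
            raise ConfigurationError("abundances must be >= 0")
        if min(self.cv_transition, self.cv_peptide, self.cv_sample, self.ip_cv) < 0:
            raise ConfigurationError("CVs must be >= 0")
        if not 0 <= self.ip_missing_rate < 1:
            raise ConfigurationError("missingness rate must lie in [0, 1)")

    def noiseless(self) -> "GroundTruth":
        return replace(self, cv_transition=0.0, cv_peptide=0.0, cv_sample=0.0, ip_cv=0.0,
                       ip_missing_rate=0.0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def preset(name: str) -> GroundTruth:
    """Documented genotype presets for the study contrasts."""
    if name == "wildtype":
        return GroundTruth(name=name, proteoform_fmol_per_ug=dict(WILDTYPE_ABUNDANCE))
    if name == "as5_ha":
        # HA-knockin: proteoform abundances as wild type; carries the true
        # interactor enrichment for IP simulations.
        return GroundTruth(
            name=name,
            proteoform_fmol_per_ug=dict(WILDTYPE_ABUNDANCE),
            ip_enriched=dict(DEFAULT_IP_ENRICHED),
        )
    if name == "delta_ex24":
        ab = dict(WILDTYPE_ABUNDANCE)
        ab["gpi"] = 0.0
        ab["tm_25b"] = WILDTYPE_ABUNDANCE["tm_25b"] * TM_UPREGULATION
        ab["tm_25c"] = WILDTYPE_ABUNDANCE["tm_25c"] * TM_UPREGULATION
        return GroundTruth(name=name, proteoform_fmol_per_ug=ab)
    if name == "recombinant_standard":
        # Per-segment pure standards at the spike-equivalent amount; every
        # segment is at 100% inclusion by definition.
        return GroundTruth(
            name=name,
            proteoform_fmol_per_ug={
                "gpi": 2.0, "silenced_25a": 2.0, "tm_25b": 2.0, "tm_25c": 2.0
            },
            inclusion_truth={"AS5+": 100.0, "25a": 100.0, "25b": 100.0, "25c": 100.0},
        )
    raise UnknownSegmentError(
        f"unknown preset {name!r}; choose from {PRESETS}"
    )


def true_total_reduction_percent(
    case: GroundTruth, control: GroundTruth
) -> float:
    """The generator's true gene-level percent reduction between presets."""
    tot_case = sum(case.proteoform_fmol_per_ug.values())
    tot_ctrl = sum(control.proteoform_fmol_per_ug.values())
    return 100.0 * (1.0 - tot_case / tot_ctrl)


def mixture_truth(fraction: float, segment: str = "25b", total: float = 2.0) -> GroundTruth:
    """Mixture of inclusion-positive and -negative standards at a known fraction.

    Models mixing a ``segment``-inclusion-positive recombinant protein with
    an inclusion-negative one at molar fraction ``fraction``; constitutive
    peptides report the total while the segment-specific peptide reports the
    positive component.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must lie in [0, 1]")
    pos, neg = {"25b": ("tm_25b", "tm_25c"), "25c": ("tm_25c", "tm_25b")}.get(
        segment, (None, None)
    )
    if pos is None:
        raise UnknownSegmentError(f"no mixture standard defined for {segment!r}")
    ab = {k: 0.0 for k in WILDTYPE_ABUNDANCE}
    ab[pos] = fraction * total
    ab[neg] = (1.0 - fraction) * total
    return GroundTruth(
        name=f"mixture_{segment}_{fraction:g}",
        proteoform_fmol_per_ug=ab,
        inclusion_truth={segment: 100.0 * fraction},
    )


# ---------------------------------------------------------------------------
# PRM assay + simulation
# ---------------------------------------------------------------------------

def build_prm_assay(seed: int = 0, peptide_cv: float = 0.15, n_fragments: int = 6) -> pd.DataFrame:
    """PRM assay for the example gene: peptides, fragments, frozen factors.

    Digests the enumerated proteoforms, keeps heavy-labelable constitutive and
    proteoform-specific peptides, and freezes per-peptide recovery factors and
    per-fragment library proportions (the synthetic spectral library) drawn
    from ``seed``.  The same assay object must be used for study samples and
    recombinant calibration runs, mirroring how a real assay is reused.
    """
    graph = gene_models.as5_toy_graph()
    pfs = gene_models.as5_proteoforms(graph)
    seen: dict[str, PeptideRecord] = {}
    for pf in pfs:
        for pep in digest(pf.aa_sequence, 0, (6, 25)):
            seen.setdefault(pep.sequence, pep)
    peptides = assign_specificity(
        list(seen.values()), pfs, acceptor_labels=gene_models.ACCEPTOR_LABELS
    )
    targets = [
        p
        for p in peptides
        if heavy_label_delta(p.sequence) is not None
        and (
            p.specificity == "constitutive"
            or (p.specificity == "proteoform_specific" and p.segment_tag in
                ("AS5+", "25a", "25b", "25c"))
        )
    ]
    targets.sort(key=lambda p: p.sequence)

    # parent short-names for light-channel abundance lookups
    named = gene_models.as5_proteoforms_by_name(graph)
    seq_by_name = {n: pf.aa_sequence for n, pf in named.items()}

    rng = np.random.default_rng(seed)
    rows = []
    for pep in targets:
        recovery = float(_lognormal(rng, peptide_cv))
        fractions = rng.dirichlet(np.full(n_fragments, 5.0))
        parents = sorted(n for n, s in seq_by_name.items() if pep.sequence in s)
        mass = peptide_mass(pep.sequence)
        for j, frac in enumerate(fractions):
            rows.append(
                {
                    "peptide": pep.sequence,
                    "charge": 2,
                    "protein": "NRXN3",
                    "specificity": pep.specificity,
                    "segment_tag": pep.segment_tag,
                    "parents": ",".join(parents),
                    "recovery_factor": recovery,
                    "fragment_ion": f"y{j + 3}",
                    "fragment_mz": precursor_mz(mass, 1) * (j + 3) / (len(pep.sequence) + 2),
                    "fragment_fraction": float(frac),
                }
            )
    return pd.DataFrame(rows)


def assay_peptide_info(assay: pd.DataFrame) -> pd.DataFrame:
    """One row per assay peptide (specificity, tag, parents, recovery)."""
    return (
        assay.drop_duplicates("peptide")[
            ["peptide", "charge", "protein", "specificity", "segment_tag", "parents",
             "recovery_factor"]
        ]
        .set_index("peptide", drop=False)
    )


def _light_fmol(truth: GroundTruth, parents: str) -> float:
    names = [p for p in parents.split(",") if p]
    return float(sum(truth.proteoform_fmol_per_ug.get(n, 0.0) for n in names))


def simulate_prm(
    truth: GroundTruth,
    design: Mapping[str, int] | Sequence[tuple[str, str]],
    assay: pd.DataFrame,
    seed: int = 0,
    control_condition: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate PRM transition tables for a sample design.

    ``design`` is either ``{condition: n_replicates}`` or an explicit list of
    ``(sample_id, condition)``.  When ``control_condition`` is given it must
    appear in the design (quantification centres on it).  Returns
    ``(prm_df, samples_df)`` in the long CSV dialect the quantification
    module reads.
    """
    if isinstance(design, Mapping):
        pairs = [
            (f"{cond}_{i + 1}", cond)
            for cond, n in design.items()
            for i in range(int(n))
        ]
    else:
        pairs = [(str(s), str(c)) for s, c in design]
    if not pairs:
        raise ConfigurationError("empty sample design")
    if control_condition is not None and control_condition not in {c for _, c in pairs}:
        raise ConfigurationError(
            f"design lacks the control condition {control_condition!r}"
        )

    rng = np.random.default_rng(seed)
    info = assay.drop_duplicates("peptide")
    frag = assay[["peptide", "fragment_ion", "fragment_fraction"]]

    prm_rows = []
    sample_rows = []
    for sample_id, condition in pairs:
        r_s = float(_lognormal(rng, truth.cv_sample))
        sample_rows.append(
            {"sample_id": sample_id, "condition": condition, "tic": BASE_TIC * r_s}
        )
        for pep_row in info.itertuples():
            light_fmol = _light_fmol(truth, pep_row.parents)
            # recovery bias applies to the endogenous channel only: the heavy
            # reference is spiked after digestion.
            light_area = (
                light_fmol * BASE_RESPONSE_PER_FMOL * pep_row.recovery_factor * r_s
            )
            heavy_area = truth.heavy_spike_fmol_per_ug * BASE_RESPONSE_PER_FMOL * r_s
            frs = frag[frag["peptide"] == pep_row.peptide]
            noise_l = _lognormal(rng, truth.cv_transition, size=len(frs))
            noise_h = _lognormal(rng, truth.cv_transition, size=len(frs))
            for (f, nl, nh) in zip(frs.itertuples(), noise_l, noise_h):
                al = light_area * f.fragment_fraction * nl
                ah = heavy_area * f.fragment_fraction * nh
                if al < truth.detection_limit_area:
                    al = 0.0
                for channel, area in (("light", al), ("heavy", ah)):
                    prm_rows.append(
                        {
                            "sample_id": sample_id,
                            "condition": condition,
                            "peptide": pep_row.peptide,
                            "charge": pep_row.charge,
                            "channel": channel,
                            "fragment_ion": f.fragment_ion,
                            "area": area,
                        }
                    )
    return pd.DataFrame(prm_rows), pd.DataFrame(sample_rows)


def simulate_recombinant_calibration(
    assay: pd.DataFrame,
    segments: Sequence[str] = ("AS5+", "25a", "25b", "25c"),
    n_replicates: int = 3,
    seed: int = 1,
    noise: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate pure 100%-inclusion recombinant standard runs per segment.

    Each segment's standard is the single proteoform carrying it, measured in
    ``n_replicates`` runs under the same assay; the condition label is the
    segment tag.  Recombinant proteins are fully translated, so even the
    silenced-in-vivo 25a peptides are detectable here.
    """
    proto = noise or preset("recombinant_standard")
    standard_of = {
        "AS5+": "gpi",
        "25a": "silenced_25a",
        "25b": "tm_25b",
        "25c": "tm_25c",
    }
    prm_parts, sample_parts = [], []
    for i, seg in enumerate(segments):
        if seg not in standard_of:
            raise UnknownSegmentError(f"no recombinant standard for segment {seg!r}")
        truth = replace(
            proto,
            name=f"recombinant_{seg}",
            proteoform_fmol_per_ug={standard_of[seg]: 2.0},
            inclusion_truth={seg: 100.0},
        )
        design = [(f"recomb_{seg}_{r + 1}", seg) for r in range(n_replicates)]
        prm, samples = simulate_prm(truth, design, assay, seed=seed + 7919 * i)
        prm_parts.append(prm)
        sample_parts.append(samples)
    return pd.concat(prm_parts, ignore_index=True), pd.concat(sample_parts, ignore_index=True)


# ---------------------------------------------------------------------------
# IP-MS simulation
# ---------------------------------------------------------------------------

def simulate_ipms(
    truth: GroundTruth,
    n_background: int = 500,
    n_per_group: int = 5,
    seed: int = 0,
    case: str = "as5_ha",
    control: str = "wildtype",
    max_peptides_per_protein: int = 5,
) -> dict:
    """Simulate an IP shotgun peptide-intensity matrix with known truth.

    Background proteins have equal expected intensity in both groups;
    ``truth.ip_enriched`` proteins are scaled by their fold change in the
    case group.  Peptide intensities carry lognormal noise (CV ``ip_cv``)
    and missing values are injected at rate ``ip_missing_rate``, biased
    toward low intensities.  Returns a dict with the peptide matrix
    (MultiIndex protein/peptide), the design, per-protein observable peptide
    counts, and the truth labels.
    """
    if truth.ip_missing_rate >= 1:
        raise ConfigurationError("missingness rate must be < 1")
    enriched = dict(truth.ip_enriched)
    rng = np.random.default_rng(seed)
    proteins = [f"BG{i:04d}" for i in range(n_background)] + sorted(enriched)
    samples = [f"{control}_{i + 1}" for i in range(n_per_group)] + [
        f"{case}_{i + 1}" for i in range(n_per_group)
    ]
    design = pd.Series(
        [control] * n_per_group + [case] * n_per_group, index=samples, name="condition"
    )

    rows = []
    index = []
    observable = {}
    sigma = _cv_to_sigma(truth.ip_cv)
    for prot in proteins:
        base = 10.0 ** rng.uniform(5.0, 8.0)
        n_pep = int(rng.integers(1, max_peptides_per_protein + 1))
        observable[prot] = int(rng.integers(max(n_pep, 5), 41))
        fold = enriched.get(prot, 1.0)
        for j in range(n_pep):
            pep_level = base * float(_lognormal(rng, 0.5))
            mean_by_sample = np.where(design.to_numpy() == case, pep_level * fold, pep_level)
            noise = (
                rng.lognormal(-0.5 * sigma * sigma, sigma, size=len(samples))
                if sigma > 0
                else np.ones(len(samples))
            )
            rows.append(mean_by_sample * noise)
            index.append((prot, f"{prot}_pep{j + 1}"))
    mat = pd.DataFrame(
        np.asarray(rows),
        index=pd.MultiIndex.from_tuples(index, names=["protein", "peptide"]),
        columns=samples,
    )

    if truth.ip_missing_rate > 0:
        flat = mat.to_numpy()
        logi = np.log2(flat)
        # missingness biased toward low intensity: logistic around the median
        # log-intensity, so the average missing probability is near the
        # configured rate while low-abundance signals drop out preferentially
        centre = np.quantile(logi, 0.5)
        p_miss = truth.ip_missing_rate * 2.0 / (1.0 + np.exp((logi - centre) / 2.0))
        mask = rng.random(flat.shape) < np.clip(p_miss, 0.0, 0.95)
        # every peptide keeps at least its largest observation
        keep = np.argmax(flat, axis=1)
        mask[np.arange(len(flat)), keep] = False
        flat = np.where(mask, np.nan, flat)
        mat = pd.DataFrame(flat, index=mat.index, columns=mat.columns)

    return {
        "matrix": mat,
        "design": design,
        "observable_counts": pd.Series(observable),
        "enriched_truth": enriched,
    }
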