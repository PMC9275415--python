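"""PRM quantification: transition areas -> light/heavy ratios -> summaries.

The quantification chain is:

1. integrate the selected transitions per sample/peptide/channel (sum of
   areas, with a minimum-transition-count detection gate on the light
   channel),
2. TIC-normalize integrated areas (each sample divided by its summed 2+..5+
   precursor intensity relative to the geometric mean across samples) --
   applied at the area level so that any per-sample injection scale cancels
   exactly inside the light/heavy ratio,
3. light/heavy ratio per peptide and sample; with the known heavy spike
   (2 fmol per ug total peptide) the ratio converts to an absolute amount,
4. log2 transform and centering relative to the control condition
   (per-peptide mean of the control samples),
5. median over a protein's peptides per sample (median taken on the log
   scale, reported back-transformed).

Inclusion percentages are calibrated against recombinant standards measured
with the same assay: the specific/constitutive ratio of a sample is divided
by the same quantity in the 100%-inclusion standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    ConfigurationError,
    MissingStandardError,
    SchemaError,
)

PRM_COLUMNS = ("sample_id", "condition", "peptide", "charge", "channel", "fragment_ion", "area")
SAMPLE_COLUMNS = ("sample_id", "condition", "tic")

DEFAULT_SPIKE_FMOL_PER_UG = 2.0
DEFAULT_MIN_TRANSITIONS = 3


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def integrate_peptide(transition_areas: Iterable[float]) -> tuple[float, int, bool]:
    """Sum transition areas for one sample/peptide/channel.

    Returns ``(area, n_nonzero_transitions, detected)``; all-zero areas are
    flagged as not detected rather than raising.
    """
    areas = np.asarray(list(transition_areas), dtype=float)
    if areas.size == 0:
        raise ValueError("at least one transition area is required")
    if (areas < 0).any():
        raise ValueError("transition areas must be non-negative")
    n = int((areas > 0).sum())
    total = float(areas.sum())
    return total, n, total > 0


def integrate(prm_df: pd.DataFrame) -> pd.DataFrame:
    """Integrate all transitions to one row per sample/peptide/channel."""
    _require_columns(prm_df, PRM_COLUMNS, "PRM measurement table")
    grouped = (
        prm_df.groupby(["sample_id", "condition", "peptide", "charge", "channel"], sort=False)
        .agg(area=("area", "sum"), n_transitions=("area", lambda a: int((np.asarray(a) > 0).sum())))
        .reset_index()
    )
    return grouped


def tic_normalize(
    values: pd.DataFrame,
    sample_tics: Mapping[str, float] | pd.Series,
    value_col: str = "area",
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each sample's values by its TIC relative to the geometric mean.

    Returns the normalized frame and the per-sample normalization factors
    (``tic / geometric_mean(tics)``), which are logged by the pipeline.
    """
    tics = pd.Series(dict(sample_tics), dtype=float)
    samples = values["sample_id"].unique()
    missing = [s for s in samples if s not in tics.index]
    if missing:
        raise ConfigurationError(f"missing TIC for sample(s): {missing}")
    if (tics <= 0).any():
        raise ConfigurationError("sample TICs must be positive")
    used = tics.loc[[s for s in tics.index if s in set(samples)]]
    geo = float(np.exp(np.log(used).mean()))
    factors = used / geo
    out = values.copy()
    out[value_col] = out[value_col] / out["sample_id"].map(factors)
    return out, factors


def light_heavy_ratio(
    light_area: float,
    heavy_area: float,
    spike_fmol_per_ug: float = DEFAULT_SPIKE_FMOL_PER_UG,
) -> tuple[float, float]:
    """Linear light/heavy ratio and the implied absolute amount (fmol/ug)."""
    if heavy_area <= 0:
        raise MissingStandardError("heavy reference area is zero: spike missing")
    ratio = light_area / heavy_area
    return ratio, ratio * spike_fmol_per_ug


def summarize_protein(peptide_values: Iterable[float]) -> tuple[float, int]:
    """Median of per-peptide linear ratios, taken on the log scale.

    For an even number of peptides the midpoint on the log scale is reported
    back-transformed (geometric midpoint).  Returns ``(summary, n_peptides)``.
    """
    vals = np.asarray([v for v in peptide_values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("at least one peptide value is required")
    if (vals <= 0).any():
        raise ValueError("ratios must be positive for log-scale summarization")
    return float(2.0 ** np.median(np.log2(vals))), int(vals.size)


@dataclass
class QuantResult:
    """Tidy outputs of the PRM pipeline.

    ``peptide_table``: one row per sample x peptide with linear ratio,
    absolute amount, log2 ratio, control-relative log2 ratio and detection
    provenance.  ``protein_table``: per-sample, per-protein median summaries.
    """

    peptide_table: pd.DataFrame
    protein_table: pd.DataFrame
    tic_factors: pd.Series
    control_condition: str | None
    spike_fmol_per_ug: float
    min_transitions: int

    def run_log(self) -> dict:
        return {
            "control_condition": self.control_condition,
            "spike_fmol_per_ug": self.spike_fmol_per_ug,
            "min_transitions": self.min_transitions,
            "tic_factors": {str(k): float(v) for k, v in self.tic_factors.items()},
            "n_peptide_rows": int(len(self.peptide_table)),
            "n_not_detected": int((~self.peptide_table["detected"]).sum()),
        }


def quantify(
    prm_df: pd.DataFrame,
    samples_df: pd.DataFrame,
    peptide_to_protein: Mapping[str, str] | None = None,
    control_condition: str | None = None,
    min_transitions: int = DEFAULT_MIN_TRANSITIONS,
    spike_fmol_per_ug: float = DEFAULT_SPIKE_FMOL_PER_UG,
) -> QuantResult:
    """Run the full PRM chain from transition areas to protein summaries."""
    _require_columns(samples_df, SAMPLE_COLUMNS, "sample table")
    integrated = integrate(prm_df)
    tics = samples_df.set_index("sample_id")["tic"]
    _, factors = tic_normalize(integrated, tics)

    wide = integrated.pivot_table(
        index=["sample_id", "condition", "peptide", "charge"],
        columns="channel",
        values=["area", "n_transitions"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()
    for col in ("area_light", "area_heavy"):
        if col not in wide.columns:
            raise SchemaError(f"PRM table lacks a {col.split('_')[1]!r} channel")
    if wide["area_heavy"].isna().any() or (wide["area_heavy"] <= 0).any():
        bad = wide.loc[
            wide["area_heavy"].isna() | (wide["area_heavy"] <= 0),
            ["sample_id", "peptide"],
        ]
        raise MissingStandardError(
            "heavy reference missing/zero for: "
            + "; ".join(f"{r.sample_id}/{r.peptide}" for r in bad.itertuples())
        )

    wide["area_light"] = wide["area_light"].fillna(0.0)
    wide["n_transitions_light"] = wide["n_transitions_light"].fillna(0).astype(int)
    wide["detected"] = (wide["area_light"] > 0) & (
        wide["n_transitions_light"] >= min_transitions
    )
    # TIC-normalized areas are reported per channel; the light/heavy ratio is
    # computed from the raw integrated areas because the per-sample TIC factor
    # divides both channels and cancels exactly (kept exact in floating point
    # by not normalizing before the quotient).
    sample_factor = wide["sample_id"].map(factors)
    wide["area_light_norm"] = wide["area_light"] / sample_factor
    wide["area_heavy_norm"] = wide["area_heavy"] / sample_factor
    wide["ratio"] = wide["area_light"] / wide["area_heavy"]
    wide["fmol_per_ug"] = wide["ratio"] * spike_fmol_per_ug
    with np.errstate(divide="ignore"):
        wide["log2_ratio"] = np.where(wide["detected"], np.log2(wide["ratio"]), np.nan)

    if control_condition is not None:
        if control_condition not in set(wide["condition"]):
            raise ConfigurationError(
                f"control condition {control_condition!r} absent from the data"
            )
        ctrl = wide[wide["condition"] == control_condition]
        centers = ctrl.groupby(["peptide", "charge"])["log2_ratio"].mean()
        key = pd.MultiIndex.from_frame(wide[["peptide", "charge"]])
        wide["ctrl_rel_log2"] = wide["log2_ratio"] - centers.reindex(key).to_numpy()
    else:
        wide["ctrl_rel_log2"] = wide["log2_ratio"]

    if peptide_to_protein is None:
        peptide_to_protein = {p: "protein" for p in wide["peptide"].unique()}
    wide["protein"] = wide["peptide"].map(dict(peptide_to_protein))

    detected = wide[wide["detected"] & wide["protein"].notna()]
    protein = (
        detected.dropna(subset=["ctrl_rel_log2"])
        .groupby(["sample_id", "condition", "protein"])
        .agg(median_log2=("ctrl_rel_log2", "median"), n_peptides=("peptide", "nunique"))
        .reset_index()
    )
    protein["linear_ratio"] = 2.0 ** protein["median_log2"]

    return QuantResult(
        peptide_table=wide,
        protein_table=protein,
        tic_factors=factors,
        control_condition=control_condition,
        spike_fmol_per_ug=spike_fmol_per_ug,
        min_transitions=min_transitions,
    )


def percent_change(
    protein_table: pd.DataFrame,
    case: str,
    control: str,
    protein: str | None = None,
) -> dict:
    """Percent reduction of a protein in ``case`` relative to ``control``.

    ``100 * (1 - mean_case / mean_control)`` over replicate-level protein
    summaries (linear control-relative ratios), with the SEM propagated by
    the delta method across both groups.  With a single replicate in either
    group the SEM is reported as NaN while the point estimate is returned.
    """
    tab = protein_table
    if protein is not None:
        tab = tab[tab["protein"] == protein]
    x1 = tab.loc[tab["condition"] == case, "linear_ratio"].to_numpy(dtype=float)
    x0 = tab.loc[tab["condition"] == control, "linear_ratio"].to_numpy(dtype=float)
    if x1.size == 0 or x0.size == 0:
        raise ConfigurationError("both conditions need at least one replicate summary")
    m1, m0 = float(x1.mean()), float(x0.mean())
    ratio = m1 / m0
    if x1.size >= 2 and x0.size >= 2:
        se1 = x1.std(ddof=1) / np.sqrt(x1.size)
        se0 = x0.std(ddof=1) / np.sqrt(x0.size)
        sem = 100.0 * ratio * float(np.sqrt((se1 / m1) ** 2 + (se0 / m0) ** 2))
    else:
        sem = float("nan")
    return {
        "percent_change": 100.0 * (1.0 - ratio),
        "sem": sem,
        "n_case": int(x1.size),
        "n_control": int(x0.size),
    }


def inclusion_percent(
    specific_ratio: float,
    constitutive_ratio: float,
    calib_specific_ratio: float,
    calib_constitutive_ratio: float,
    warn_above: float = 150.0,
) -> float:
    """Splice-site inclusion % calibrated to a 100%-inclusion standard.

    ``I = 100 * (R_spec/R_const)_sample / (R_spec/R_const)_standard``.  A
    not-detected specific peptide enters as ratio 0 and yields 0%.  Values
    may exceed 100 from noise; they are reported uncapped with a warning
    above ``warn_above``.
    """
    if constitutive_ratio <= 0:
        raise ValueError("constitutive ratio must be positive")
    if calib_specific_ratio <= 0 or calib_constitutive_ratio <= 0:
        raise CalibrationError("recombinant calibration ratios must be positive")
    value = 100.0 * (specific_ratio / constitutive_ratio) / (
        calib_specific_ratio / calib_constitutive_ratio
    )
    if value > warn_above:
        warnings.warn(
            f"inclusion {value:.1f}% exceeds {warn_above:.0f}%; check calibration",
            stacklevel=2,
        )
    return value


def _geomean_ratio(df: pd.DataFrame, peptides: Sequence[str]) -> pd.Series:
    """Per-sample geometric-mean ratio over detected peptides of a set."""
    sub = df[df["peptide"].isin(peptides) & df["detected"]]
    if sub.empty:
        return pd.Series(dtype=float)
    return sub.groupby("sample_id")["ratio"].apply(
        lambda r: float(np.exp(np.log(r[r > 0]).mean())) if (r > 0).any() else 0.0
    )


def inclusion_table(
    quant: QuantResult,
    calibration: QuantResult,
    segment_peptides: Mapping[str, Sequence[str] | str],
    constitutive_peptides: Sequence[str],
    warn_above: float = 150.0,
) -> pd.DataFrame:
    """Per-sample inclusion % for each segment, calibrated per segment.

    ``segment_peptides`` maps segment tags to the proteoform-specific
    peptide(s) reporting that segment; ``calibration`` is a
    :class:`QuantResult` of recombinant 100%-inclusion standards in which the
    segment's sample condition is the segment tag (or a single condition
    covering all segments).
    """
    rows = []
    pep_tab = quant.peptide_table
    const_sample = _geomean_ratio(pep_tab, list(constitutive_peptides))
    for segment, peps in segment_peptides.items():
        if isinstance(peps, str):
            peps = [peps]
        calib_tab = calibration.peptide_table
        seg_calib = calib_tab[calib_tab["condition"].isin([segment, "recombinant"])]
        calib_spec = _geomean_ratio(seg_calib, list(peps))
        calib_const = _geomean_ratio(seg_calib, list(constitutive_peptides))
        common = calib_spec.index.intersection(calib_const.index)
        if common.empty or not (calib_spec.loc[common] > 0).any():
            raise CalibrationError(
                f"no recombinant calibration available for segment {segment!r}"
            )
        calib_factor = float(
            np.median(
                (calib_spec.loc[common] / calib_const.loc[common])[
                    calib_spec.loc[common] > 0
                ]
            )
        )
        spec_sample = _geomean_ratio(pep_tab, list(peps))
        for sample_id in const_sample.index:
            const_r = const_sample.loc[sample_id]
            spec_r = float(spec_sample.get(sample_id, 0.0))
            detected = spec_r > 0
            value = (
                inclusion_percent(spec_r, const_r, calib_factor, 1.0, warn_above)
                if detected
                else 0.0
            )
            cond = pep_tab.loc[pep_tab["sample_id"] == sample_id, "condition"].iloc[0]
            rows.append(
                {
                    "sample_id": sample_id,
                    "condition": cond,
                    "segment": segment,
                    "inclusion_percent": value,
                    "provenance": "detected" if detected else "not_detected",
                }
            )
    return pd.DataFrame(rows)
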