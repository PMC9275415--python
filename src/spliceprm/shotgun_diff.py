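"""Differential enrichment analysis of affinity-purification shotgun data.

Peptide intensity matrices (peptides x samples, missing values allowed) are
kNN-imputed on the log2 scale, rolled up to proteins by summation, converted
to iBAQ (intensity divided by the count of theoretically observable tryptic
peptides), and tested for case-vs-control differences with an empirical-Bayes
moderated t-test: per-protein residual variances are shrunk toward a pooled
prior estimated by matching moments of the scaled-F distribution of sample
variances, the moderated t uses the shrunken standard error, and p-values
come from a t-distribution with prior-augmented degrees of freedom.
Multiplicity is handled with Benjamini-Hochberg (default) or the two-stage
Benjamini-Krieger-Yekutieli step-up.  Interactors are proteins passing a
strict fold-change and q-value screen (defaults: fold change > 2.0, q < 0.05).

Between-sample normalization is OFF by default: in IP experiments the control
precipitates carry genuinely little material, so equalizing totals would
erase the signal.  Opt in with ``normalize=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, SchemaError


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing entries from the k nearest peptide rows.

    Distances are Euclidean over co-observed log2 intensities; the filled
    value is the distance-weighted mean of the neighbours' observed log2
    intensities, back-transformed.  Observed entries are untouched.  Rows
    with no observed value are dropped with a warning; ``k`` is clipped to
    the number of other rows with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    full_missing = matrix.isna().all(axis=1)
    if full_missing.any():
        warnings.warn(
            f"dropping {int(full_missing.sum())} fully missing row(s)", stacklevel=2
        )
        matrix = matrix.loc[~full_missing]
    if not matrix.isna().any().any():
        return matrix.copy()
    n_rows = len(matrix)
    k_eff = min(k, n_rows - 1) if n_rows > 1 else 1
    if k_eff < k:
        warnings.warn(f"k={k} clipped to {k_eff} (only {n_rows} rows)", stacklevel=2)
    log2 = np.log2(matrix.to_numpy(dtype=float))
    imputer = KNNImputer(n_neighbors=k_eff, weights="distance", metric="nan_euclidean")
    filled = imputer.fit_transform(log2)
    return pd.DataFrame(2.0 ** filled, index=matrix.index, columns=matrix.columns)


def rollup_protein(matrix: pd.DataFrame, protein_level: str = "protein") -> pd.DataFrame:
    """Sum peptide intensities per protein and sample."""
    if protein_level not in (matrix.index.names or []):
        raise SchemaError(
            f"peptide matrix index must carry a {protein_level!r} level"
        )
    return matrix.groupby(level=protein_level, sort=True).sum()


def ibaq(
    protein_intensity: pd.DataFrame,
    observable_counts: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """iBAQ: protein intensity divided by its observable tryptic peptide count.

    Proteins with a zero/missing count are excluded with a warning.
    """
    counts = pd.Series(dict(observable_counts), dtype=float).reindex(protein_intensity.index)
    bad = counts.isna() | (counts <= 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} protein(s) without observable peptides",
            stacklevel=2,
        )
    kept = protein_intensity.loc[~bad]
    return kept.div(counts.loc[~bad], axis=0)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_scaled_f(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed sample variances.

    Returns ``(prior_df, prior_s2)``: the prior degrees of freedom d0 and
    location s0^2 such that s2 ~ s0^2 * F(df, d0).  d0 is infinite when the
    variances show no excess dispersion beyond chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("no positive variances to fit")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def moderated_test(
    log2_matrix: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    case: str,
    control: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per protein.

    ``log2_matrix``: proteins x samples of log2 intensities.  ``design`` maps
    sample -> condition.  ``prior_df`` overrides the estimated prior degrees
    of freedom (0 recovers the ordinary pooled-variance t-test; ``np.inf``
    fixes every variance at the pooled prior).
    """
    design = pd.Series(dict(design))
    case_samples = [s for s in log2_matrix.columns if design.get(s) == case]
    ctrl_samples = [s for s in log2_matrix.columns if design.get(s) == control]
    n1, n2 = len(case_samples), len(ctrl_samples)
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("each condition needs >= 2 replicates for testing")
    df_resid = n1 + n2 - 2
    x1 = log2_matrix[case_samples].to_numpy(dtype=float)
    x2 = log2_matrix[ctrl_samples].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    log2_fc = m1 - m2

    if prior_df is None:
        d0, s0 = fit_scaled_f(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0 = fit_scaled_f(s2, df_resid) if d0 > 0 else (None, float(np.mean(s2)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
    elif d0 == 0:
        s2_post = s2
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2_fc / se
    df_total = df_resid + d0
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t": t,
            "p": p,
            "s2": s2,
            "s2_post": s2_post,
            "df_prior": d0,
            "df_total": df_total,
        },
        index=log2_matrix.index,
    )


def adjust_multiplicity(p_values, method: str = "bh") -> np.ndarray:
    """Step-up adjusted q-values: ``bh`` or two-stage ``bky``."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    methods = {"bh": "fdr_bh", "bky": "fdr_tsbky"}
    if method not in methods:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(methods)}")
    return multipletests(p, method=methods[method])[1]


def enrichment_filter(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Interactors: linear fold change strictly > threshold AND q strictly < threshold."""
    fc = 2.0 ** results["log2_fc"]
    passing = results[(fc > fc_threshold) & (results["q"] < q_threshold)].copy()
    passing["fold_change"] = 2.0 ** passing["log2_fc"]
    return passing.sort_values(["q", "fold_change"], ascending=[True, False])


@dataclass
class EnrichmentResult:
    protein_table: pd.DataFrame
    interactors: pd.DataFrame
    ibaq_table: pd.DataFrame


def differential_enrichment(
    peptide_matrix: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    observable_counts: Mapping[str, int] | pd.Series,
    case: str,
    control: str,
    k: int = 10,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    q_method: str = "bh",
    normalize: bool = False,
    specificity: Mapping[str, str] | None = None,
) -> EnrichmentResult:
    """Full IP-MS chain: impute -> roll up -> iBAQ -> moderated test -> filter.

    ``peptide_matrix`` carries a (protein, peptide) MultiIndex and one column
    per sample.  ``specificity`` optionally maps peptides to their
    specificity class; when given, only ``proteoform_specific`` and
    ``constitutive`` peptide signals enter the roll-up (isoform-resolved
    quantification).
    """
    mat = peptide_matrix
    if specificity is not None:
        keep = [
            p
            for p in mat.index.get_level_values("peptide")
            if specificity.get(p) in ("proteoform_specific", "constitutive")
        ]
        mat = mat[mat.index.get_level_values("peptide").isin(keep)]
    if normalize:
        totals = mat.sum(axis=0, skipna=True)
        geo = np.exp(np.log(totals[totals > 0]).mean())
        mat = mat.div(totals / geo, axis=1)
    imputed = knn_impute(mat, k=k)
    protein = rollup_protein(imputed)
    ibaq_tab = ibaq(protein, observable_counts)
    log2_tab = np.log2(ibaq_tab)
    res = moderated_test(log2_tab, design, case=case, control=control)
    res["q"] = adjust_multiplicity(res["p"].to_numpy(), method=q_method)
    res["ibaq_mean_case"] = ibaq_tab[
        [s for s in ibaq_tab.columns if dict(design).get(s) == case]
    ].mean(axis=1)
    res["ibaq_mean_control"] = ibaq_tab[
        [s for s in ibaq_tab.columns if dict(design).get(s) == control]
    ].mean(axis=1)
    res["pass"] = (2.0 ** res["log2_fc"] > fc_threshold) & (res["q"] < q_threshold)
    interactors = enrichment_filter(res, fc_threshold, q_threshold)
    return EnrichmentResult(protein_table=res, interactors=interactors, ibaq_table=ibaq_tab)
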