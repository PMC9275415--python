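"""Calibrated splice-site inclusion % across known standard mixtures.

Mixes inclusion-positive and inclusion-negative recombinant standards at
known molar fractions, measures them with the simulated PRM assay, and
calibrates the specific/constitutive ratio against the pure 100%-inclusion
standard.  Run: python examples/04_inclusion_calibration.py
"""

import numpy as np

from spliceprm import inclusion_table, quantify
from spliceprm import synthetic_data as syn

assay = syn.build_prm_assay(seed=0)
info = syn.assay_peptide_info(assay)
constitutive = list(info.loc[info["specificity"] == "constitutive", "peptide"])
segment_peptides = {"25b": list(info.loc[info["segment_tag"] == "25b", "peptide"])}

n_repeats = 10
print(f"acceptor-25b inclusion, 5 samples per mixture, {n_repeats} repeated experiments:")
print("  true %   estimated % (mean +/- sd over experiments)")
for fraction in (0.0, 0.25, 0.50, 0.75, 1.0):
    truth = syn.mixture_truth(fraction, "25b")
    estimates = []
    for rep in range(n_repeats):
        calib_prm, calib_samples = syn.simulate_recombinant_calibration(
            assay, segments=("25b",), n_replicates=3, seed=11 + 31 * rep
        )
        calibration = quantify(calib_prm, calib_samples)
        prm, samples = syn.simulate_prm(
            truth, {"mix": 5}, assay, seed=100 * rep + int(fraction * 100)
        )
        tab = inclusion_table(
            quantify(prm, samples), calibration, segment_peptides, constitutive
        )
        estimates.append(tab["inclusion_percent"].mean())
    print(f"  {100 * fraction:6.1f}   {np.mean(estimates):6.1f} +/- {np.std(estimates):4.1f}")

print(
    "\nThe ratio-of-ratios calibration cancels peptide-specific response and"
    "\nrecovery factors, so the estimates track the true molar inclusion"
    "\nfraction (values can exceed 100% from noise and are reported uncapped);"
    "\na not-detected specific peptide reports 0% with provenance."
)
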