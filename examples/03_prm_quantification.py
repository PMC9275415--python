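"""Quantify the knockout's total-protein reduction from simulated PRM data.

Simulates a 5-vs-5 wild-type vs exon-24-knockout PRM experiment with the
default noise model, runs the full quantification chain (transition
integration, heavy-reference ratios, TIC normalization, control-relative
log ratios, per-protein medians) and reports the percent reduction of total
gene-level protein.  Run: python examples/03_prm_quantification.py
"""

import pandas as pd

from spliceprm import percent_change, quantify
from spliceprm import synthetic_data as syn

assay = syn.build_prm_assay(seed=0)
info = syn.assay_peptide_info(assay)
protein_map = {
    p: "NRXN3" for p in info.loc[info["specificity"] == "constitutive", "peptide"]
}

wildtype = syn.preset("wildtype")
knockout = syn.preset("delta_ex24")
print("ground truth (fmol/ug):")
print(f"  wild type: {wildtype.proteoform_fmol_per_ug}")
print(f"  knockout : {knockout.proteoform_fmol_per_ug}")
true_pc = syn.true_total_reduction_percent(knockout, wildtype)
print(f"  true total-protein reduction: {true_pc:.1f}%\n")

prm_w, s_w = syn.simulate_prm(wildtype, {"wildtype": 5}, assay, seed=1)
prm_k, s_k = syn.simulate_prm(knockout, {"delta_ex24": 5}, assay, seed=2)
quant = quantify(
    pd.concat([prm_w, prm_k]), pd.concat([s_w, s_k]),
    protein_map, control_condition="wildtype",
)

print("per-sample protein summaries (control-relative linear ratios):")
print(quant.protein_table[["sample_id", "condition", "linear_ratio", "n_peptides"]]
      .to_string(index=False))

res = percent_change(quant.protein_table, "delta_ex24", "wildtype")
print(
    f"\nestimated reduction: {res['percent_change']:.1f} +/- {res['sem']:.1f} % "
    f"(SEM, {res['n_case']}v{res['n_control']})"
)
print(
    "The estimate recovers the generator truth: losing the GPI proteoform"
    "\nwhile mildly up-regulating the transmembrane forms reduces total"
    "\nprotein by about 61%, measured on constitutive peptides present in"
    "\nevery proteoform."
)
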