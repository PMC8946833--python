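"""Relative qPCR quantification with the 2^-ddCt method.

Simulates a TaqMan Cq table for the H2AX-phosphorylation network genes (ATM,
ATR, PP4, CCDC6; 18S as reference) with known true log2 fold changes, runs
the ddCt analysis, and compares estimated with configured values.
"""

from gammahq import SimQpcrParams, analyze_qpcr, generate_qpcr_table

params = SimQpcrParams(n_replicates=6, cq_noise_sd=0.15, rng_seed=8)
table = generate_qpcr_table(params)
print(f"Cq table: {len(table)} measurements "
      f"({params.n_replicates} samples x 2 conditions x "
      f"{len(params.genes) + 1} genes x {params.n_technical} technical reps)\n")

results = analyze_qpcr(table, reference_gene=params.reference_gene)
results["true_log2_fc"] = results["gene"].map(params.true_log2_fc)
print(results[["gene", "ddct", "fold_change", "log2_fc", "true_log2_fc",
               "n_excluded"]].to_string(index=False))

# log2_fc = -ddct; fold_change = 2^-ddct.  A negative log2 fold change
# (ATM, ATR, CCDC6) means fewer transcripts after osmotic stress, i.e. a
# higher normalized Cq in the treated condition.
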