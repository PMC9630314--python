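"""Simulate three cohorts in different units and harmonise to pseudo-TPM.

Builds FPKM / RSEM-fraction / TPM cohorts sharing a 6-gene correlated
module, converts each to TPM, merges on the common gene symbols and
rescales each sample to a one-million total.  Prints the per-cohort
summary of one module gene.
"""

import coexnet as cx

module = cx.ModuleSpec("core", tuple(f"MOD{i}" for i in range(6)), 0.8)
specs = [
    cx.CohortSpec("mCRPC_A", n_samples=60, unit="FPKM", seed=1),
    cx.CohortSpec("mCRPC_B", n_samples=40, unit="RSEM_FRACTION", seed=2),
    cx.CohortSpec("benign", n_samples=50, unit="TPM", seed=3),
]
cohorts = cx.generate_multicohort(
    specs, [module], per_cohort_extra_genes=5, n_background_genes=40
)
merged = cx.merge_cohorts([cx.to_tpm(m) for m in cohorts])

print(f"common genes: {merged.n_common_genes}, samples: {len(merged.samples)}")
print(f"column sums (pseudo-TPM): {merged.values.sum(axis=0).round(6).unique()}")
for row in cx.summarize_gene(merged, "MOD0", seed=0):
    print(
        f"{row.cohort}: n={row.n} median={row.median:.1f} "
        f"IQR=[{row.q1:.1f}, {row.q3:.1f}] 95% CI=({row.ci_low:.1f}, {row.ci_high:.1f})"
    )
# Each line is one cohort's distribution of the gene on the shared
# pseudo-TPM scale; the CI is a seeded bootstrap of the median.
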