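"""Detect allelic heterogeneity: multiple independent eQTLs at one gene.

Plants two causal SNPs in different LD blocks for every gene, then compares
the conditional-BF tier scan with forward-stepwise/BIC selection.
"""

from eqtlcre.pipeline import residualize_study, significant_records
from eqtlcre.simulate import simulate_study_set
from eqtlcre.tiers import forward_stepwise_bic, ld_blocks, permutation_fdr

study = simulate_study_set(n_genes=30, n_samples=300, seed=12,
                           effect_r2=0.15, eqtl_fraction=1.0,
                           two_tier_fraction=1.0)
residuals, _ = residualize_study(study.expression["A_discovery"], 10, 0.01)
blocks = {c: ld_blocks(r).block_index for c, r in study.rmaps.items()}
fdr, records = permutation_fdr(residuals, study.genotypes["A_discovery"],
                               study.gene_models, blocks, seed=13)
sig = significant_records(records,
                          {t: fdr.cutoff_at(0.1, t) for t in range(1, 5)})

ah_genes = sig.groupby("GENE").filter(lambda g: g["TIER"].max() >= 2)
print(f"{ah_genes['GENE'].nunique()} / {study.gene_models.shape[0]} genes "
      "show allelic heterogeneity (two independent tiers) at FDR 10%")

agree = total = 0
gmi = study.gene_models.set_index("gene_id")
for gene_id in study.gene_models["gene_id"]:
    gt = study.genotypes["A_discovery"][gmi.loc[gene_id, "chrom"]]
    bl = blocks[gmi.loc[gene_id, "chrom"]]
    sel = forward_stepwise_bic(residuals[gene_id].to_numpy(), gt.dosages)
    n_stepwise = len({bl[j] for j in sel})
    n_tiers = len(sig[sig["GENE"] == gene_id])
    agree += int(n_stepwise == n_tiers)
    total += 1
print(f"stepwise/BIC agrees with the tier count (independent signals) at "
      f"{agree}/{total} genes")
# Both methods count independent association signals; stepwise may select
# several tag SNPs inside one LD block, so its selections are collapsed to
# distinct blocks before comparison.
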