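"""Predict cell-type-specific eQTL replication from CRE features.

Runs the full pipeline on a study where specificity is driven by fully
cell-type-specific CRE tracks, then reports the cross-validated AUC for the
cell-specific task with and without CRE feature columns.
"""

from eqtlcre.config import PipelineConfig
from eqtlcre.pipeline import run_pipeline

cfg = PipelineConfig(n_genes=100, n_samples=200, seed=31,
                     cre_specific_fraction=1.0, cre_eqtl_enrichment=6.0,
                     n_trees=200)
result = run_pipeline(cfg)

for task, rep in result.classifier.items():
    print(f"{task:>14s}: AUC = {rep['auc']:.3f} "
          f"(without CRE features: {rep['auc_without_cre']:.3f}, "
          f"delta = {rep['delta_auc']:+.3f})")
# A positive delta means matched/unmatched CRE overlap carries information
# about replication beyond the positional and effect-size features.
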