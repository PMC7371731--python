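"""Shared study configuration for the analysis drivers.

One place defines the simulated study conditions every driver uses:
cohorts of 20 samples per outcome group, 200 genes with a 20-gene planted
senescence block shifted by 2 within-group SDs, exponential survival with
a log hazard ratio of -0.9 per unit of standardized signature score
(high-signature samples survive longer), censored at the 100-day
observation horizon, everything seeded with 1.
"""

from suvarness.simulate import CohortConfig
from suvarness.workflows import PipelineConfig

SEED = 1

STUDY = PipelineConfig(
    cohort=CohortConfig(
        n_genes=200,
        n_samples_per_group={"NR": 20, "RP": 20},
        n_signature_genes=20,
        effect_size=2.0,
        hazard_rate=0.03,
        hazard_log_hr=-0.9,
        censor_horizon=100.0,
        seed=SEED,
    ),
    n_classifier_genes=15,
    cv_folds=10,
    cv_seed=SEED,
    gsea_permutations=1000,
    gsea_seed=SEED,
)
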