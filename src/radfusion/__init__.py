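"""radfusion: fusing engineered radiomics and CNN transfer-learning
feature banks for two-year survival prognosis.

The package implements a stacked risk-score fusion model — per-bank
random forests whose out-of-fold death probabilities feed a second-stage
forest — together with the four feature fusion/reduction baselines it is
benchmarked against (PCA, Boruta, univariate Cox screening,
correlation-cutoff + LASSO), the evaluation statistics (AUC with DeLong
intervals and paired tests, Youden thresholds, BH-FDR, FWER), SMOTE
class balancing, both feature-extraction front ends (a 1428-feature
engineered bank and a 64-unit CNN bank), and a synthetic-cohort
generator that emulates the statistical structure of the original
two-hospital pancreatic-cancer study.
"""

from .catalog import FeatureCatalog, build_feature_catalog
from .correlation import (
    CorrelationSummary,
    aggregate_by_group,
    pairwise_pearson,
    summarize_bank_correlation,
)
from .cox import CoxFit, fit_univariate_cox, univariate_cox_screen
from .deep import (
    ArchitectureSpec,
    LungStyleCNN,
    TrainConfig,
    extract_deep_features,
    filter_zero_variance,
    preprocess_roi,
    pretrain,
    select_largest_roi_slice,
)
from .evaluation import (
    AUCResult,
    bh_adjust,
    delong_ci,
    delong_paired_test,
    evaluate_scores,
    fwer,
    roc_auc,
    youden_threshold,
)
from .fusion import (
    BenchmarkConfig,
    FusionResult,
    RFConfig,
    fuse_pca,
    riskscore_fit,
    riskscore_predict,
    run_benchmark,
    select_boruta,
    select_lasso,
    select_univariate_cox,
)
from .radiomics import (
    IntensityMaskRule,
    apply_intensity_mask,
    extract_radiomics,
    validate_feature_table,
)
from .smote import SmoteConfig, smote_balance
from .synthetic import (
    SimulationConfig,
    SurvivalRecord,
    derive_two_year_label,
    generate_cohort,
    generate_roi_images,
    study_cohorts,
)

__version__ = "0.1.0"
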