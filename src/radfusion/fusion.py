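"""The five prognosis pipelines: four fusion/reduction baselines and
risk-score stacking.

All five consume the same pair of training feature banks (engineered
bank R, deep bank T) with a binary two-year outcome, and produce a
per-sample death probability on a held-out test cohort:

* ``pca`` — unsupervised fusion: PCA on the standardized concatenated
  banks, components covering 95% variance, random forest on components;
* ``boruta`` — all-relevant selection against shadow features, forest on
  the confirmed set;
* ``cox`` — univariate proportional-hazards screen at p < 0.05 (no
  multiplicity correction), forest on the significant set;
* ``lasso`` — greedy |r| > 0.7 redundancy filter, then L1 logistic
  regression with cross-validated penalty, forest on the support;
* ``riskscore`` — the stacked model: per-bank forests produce
  out-of-fold death probabilities on the training cohort, and a meta
  forest on that 2-dimensional risk-score space makes the final call.

Class imbalance is handled by SMOTE on every forest's training data —
inside each cross-validation fold for the stacked base models (never on
held-out data) and on the full training cohort before final fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .cox import univariate_cox_screen, fit_univariate_cox
from .evaluation import AUCResult, bh_adjust, delong_paired_test, evaluate_scores, roc_auc
from .smote import SmoteConfig, smote_balance

logger = logging.getLogger(__name__)

__all__ = [
    "RFConfig",
    "RiskScoreBundle",
    "FusionResult",
    "fuse_pca",
    "select_boruta",
    "select_univariate_cox",
    "select_lasso",
    "riskscore_fit",
    "riskscore_predict",
    "run_benchmark",
    "BenchmarkConfig",
]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings: 500 trees; mtry 2 for the component/meta
    models and 310 for the Cox pipeline (clamped to the feature count)."""

    n_trees: int = 500
    mtry: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.mtry < 1:
            raise ValueError("n_trees and mtry must be >= 1")


def _rf(config: RFConfig, n_features: int, seed_offset: int = 0) -> RandomForestClassifier:
    mtry = min(config.mtry, n_features)
    if mtry != config.mtry:
        logger.info("mtry %d clamped to %d features", config.mtry, n_features)
    return RandomForestClassifier(
        n_estimators=config.n_trees, max_features=mtry,
        random_state=(config.seed + seed_offset) % (2 ** 31), n_jobs=1)


def _death_proba(model: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    idx = int(np.flatnonzero(model.classes_ == 1)[0])
    return model.predict_proba(x)[:, idx]


@dataclass
class FusionResult:
    method: str
    selected: list
    test_scores: np.ndarray
    auc_result: AUCResult | None = None


# ----------------------------------------------------------------- PCA fusion

def fuse_pca(train_r: pd.DataFrame, train_t: pd.DataFrame,
             test_r: pd.DataFrame, test_t: pd.DataFrame,
             labels, var_threshold: float = 0.95,
             rf: RFConfig = RFConfig(mtry=2),
             smote: SmoteConfig = SmoteConfig()) -> FusionResult:
    """Unsupervised fusion: minimal component set covering the variance
    threshold, fitted on the standardized training banks only."""
    if not 0.0 < var_threshold <= 1.0:
        raise ValueError("var_threshold must lie in (0, 1]")
    train = pd.concat([train_r, train_t], axis=1)
    test = pd.concat([test_r, test_t], axis=1)
    scaler = StandardScaler().fit(train)
    zt = scaler.transform(train)
    pca = PCA(random_state=rf.seed).fit(zt)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    comps_train = pca.transform(zt)[:, :n_comp]
    comps_test = pca.transform(scaler.transform(test))[:, :n_comp]
    xb, yb = smote_balance(comps_train, labels, smote)
    model = _rf(rf, n_comp).fit(xb, yb)
    return FusionResult("pca", [f"PC{i + 1}" for i in range(n_comp)],
                        _death_proba(model, comps_test))


def n_components_for_variance(train: pd.DataFrame, var_threshold: float = 0.95) -> int:
    """Smallest PCA component count reaching the variance threshold."""
    z = StandardScaler().fit_transform(train)
    cum = np.cumsum(PCA().fit(z).explained_variance_ratio_)
    return int(np.searchsorted(cum, var_threshold - 1e-12) + 1)


# -------------------------------------------------------------------- Boruta

def select_boruta(train_features: pd.DataFrame, labels, max_iter: int = 100,
                  alpha: float = 0.05, rf: RFConfig = RFConfig(), seed: int = 0,
                  n_trees: int | None = None) -> list[str]:
    """All-relevant feature selection against shadow features.

    Each iteration appends a shuffled copy of every undecided feature,
    fits a random forest, and scores a "hit" for features more important
    than the best shadow.  Two-sided binomial tests (Bonferroni-adjusted
    at ``alpha``) confirm or reject features as the iterations
    accumulate; features still tentative at the end are resolved by
    requiring both a positive median importance margin over the best
    shadow and a nominally significant hit record.
    """
    if max_iter < 5:
        raise ValueError("max_iter must be >= 5 for the binomial test to make sense")
    x = train_features.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    names = list(train_features.columns)
    p = len(names)
    if p < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)

    undecided = np.ones(p, dtype=bool)
    confirmed = np.zeros(p, dtype=bool)
    hits = np.zeros(p, dtype=int)
    tested = 0
    # margin vs the iteration's best shadow; importances are only
    # comparable within an iteration (the active set shrinks over time)
    margin_history: list[np.ndarray] = []

    for _ in range(max_iter):
        active = np.flatnonzero(undecided | confirmed)
        if not undecided.any():
            break
        xa = x[:, active]
        # the shadow pool stays at full width even as real features are
        # dropped, so the max-shadow null envelope keeps its severity
        shadow = x.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        forest = RandomForestClassifier(
            n_estimators=n_trees or rf.n_trees, max_features="sqrt",
            random_state=int(rng.integers(2 ** 31)), n_jobs=1)
        forest.fit(np.hstack([xa, shadow]), y)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[:xa.shape[1]], imp[xa.shape[1]:]
        shadow_max = shadow_imp.max()
        row = np.full(p, np.nan)
        row[active] = real_imp - shadow_max
        margin_history.append(row)
        hits[active] += (real_imp > shadow_max).astype(int)
        tested += 1
        if tested >= 5:
            m = p  # Bonferroni over the full feature set
            for j in np.flatnonzero(undecided):
                p_hi = stats.binomtest(hits[j], tested, 0.5, alternative="greater").pvalue
                p_lo = stats.binomtest(hits[j], tested, 0.5, alternative="less").pvalue
                if p_hi < alpha / m:
                    confirmed[j] = True
                    undecided[j] = False
                elif p_lo < alpha / m:
                    undecided[j] = False  # rejected

    if undecided.any():
        # tentative resolution: positive median margin over the best
        # shadow AND a nominally significant (unadjusted) hit record
        hist = np.vstack(margin_history)
        for j in np.flatnonzero(undecided):
            med = np.nanmedian(hist[:, j])
            p_hit = stats.binomtest(hits[j], tested, 0.5, alternative="greater").pvalue
            if np.isfinite(med) and med > 0 and p_hit < alpha:
                confirmed[j] = True
    return [names[j] for j in np.flatnonzero(confirmed)]


# ------------------------------------------------------------------ Cox / L1

def select_univariate_cox(train_features: pd.DataFrame, time_days, event,
                          alpha: float = 0.05) -> list[str]:
    """Proportional-hazards screen: features with Wald p < alpha."""
    return univariate_cox_screen(train_features.to_numpy(dtype=float),
                                 time_days, event, alpha=alpha,
                                 feature_names=list(train_features.columns))


def correlation_filter(train_features: pd.DataFrame, corr_cutoff: float = 0.7) -> list[str]:
    """Greedy redundancy filter.

    While any pair exceeds the cutoff, take the currently worst pair and
    drop its member with the larger mean |r| against all remaining
    features (ties drop the later column).  Survivors have max pairwise
    |r| <= cutoff.
    """
    cols = list(train_features.columns)
    r = np.abs(np.corrcoef(train_features.to_numpy(dtype=float), rowvar=False))
    np.fill_diagonal(r, 0.0)
    r = np.nan_to_num(r)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = np.where(np.outer(alive, alive), r, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= corr_cutoff:
            break
        mean_i = sub[i, alive].mean()
        mean_j = sub[j, alive].mean()
        if mean_i == mean_j:
            drop = max(i, j)
        else:
            drop = i if mean_i > mean_j else j
        alive[drop] = False
    return [c for c, a in zip(cols, alive) if a]


def select_lasso(train_features: pd.DataFrame, labels, corr_cutoff: float = 0.7,
                 cv: int = 10, seed: int = 0) -> list[str]:
    """Redundancy filter followed by L1 logistic regression.

    The penalty is chosen by cross-validated log-loss; features with
    nonzero coefficients at the chosen penalty are returned.
    """
    survivors = correlation_filter(train_features, corr_cutoff)
    if not survivors:
        raise ValueError("no features survive the correlation filter")
    x = StandardScaler().fit_transform(train_features[survivors])
    y = np.asarray(labels).astype(int)
    n_folds = min(cv, int(np.bincount(y).min()))
    model = LogisticRegressionCV(
        Cs=np.logspace(-2.5, 2, 25), cv=n_folds, penalty="l1",
        solver="liblinear", scoring="neg_log_loss", random_state=seed,
        max_iter=5000).fit(x, y)
    nz = np.flatnonzero(np.abs(model.coef_[0]) > 1e-10)
    selected = [survivors[j] for j in nz]
    if not selected:
        # fully sparse solution (null data): keep the single feature with
        # the strongest marginal association so a forest can still be fit
        corr = np.abs([np.corrcoef(x[:, j], y)[0, 1] for j in range(x.shape[1])])
        selected = [survivors[int(np.nanargmax(corr))]]
        logger.warning("LASSO support empty; falling back to %s", selected[0])
    return selected


# ------------------------------------------------------------ risk-score stack

@dataclass
class RiskScoreBundle:
    model_r: RandomForestClassifier
    model_t: RandomForestClassifier
    meta_model: RandomForestClassifier
    train_pairs: pd.DataFrame  # sample_id-indexed p_bankR, p_bankT, fold_id
    columns_r: list[str]
    columns_t: list[str]


def riskscore_fit(train_r: pd.DataFrame, train_t: pd.DataFrame, labels,
                  folds: int = 10, rf: RFConfig = RFConfig(mtry=2),
                  smote: SmoteConfig = SmoteConfig(), seed: int = 0) -> RiskScoreBundle:
    """Fit the stacked risk-score model.

    Stratified out-of-fold probabilities from per-bank forests form the
    training risk scores; the meta forest (mtry = 2 over the two scores)
    is trained on them.  Every fold's base forests see SMOTE-balanced
    data from the other folds only, so no training risk score ever comes
    from a model that saw that sample.
    """
    y = np.asarray(labels).astype(int)
    if not train_r.index.equals(train_t.index):
        raise ValueError("bank R and bank T must be row-aligned")
    n_minority = int(np.bincount(y).min())
    if folds < 2 or folds > n_minority:
        raise ValueError(f"folds must lie in [2, n_minority={n_minority}]")

    xr = train_r.to_numpy(dtype=float)
    xt = train_t.to_numpy(dtype=float)
    oof = pd.DataFrame(index=train_r.index, columns=["p_bankR", "p_bankT", "fold_id"],
                       dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2 ** 31))
    base_rf = replace(rf, mtry=max(int(np.sqrt(xr.shape[1])), 1))
    for fold_id, (fit_idx, held_idx) in enumerate(skf.split(xr, y)):
        for bank, x in (("p_bankR", xr), ("p_bankT", xt)):
            xb, yb = smote_balance(x[fit_idx], y[fit_idx],
                                   replace(smote, seed=smote.seed + fold_id))
            mtry = max(int(np.sqrt(x.shape[1])), 1)
            model = _rf(replace(rf, mtry=mtry), x.shape[1], seed_offset=fold_id + 1).fit(xb, yb)
            oof.loc[train_r.index[held_idx], bank] = _death_proba(model, x[held_idx])
        oof.loc[train_r.index[held_idx], "fold_id"] = fold_id

    xb, yb = smote_balance(xr, y, smote)
    model_r = _rf(replace(rf, mtry=max(int(np.sqrt(xr.shape[1])), 1)), xr.shape[1]).fit(xb, yb)
    xb, yb = smote_balance(xt, y, smote)
    model_t = _rf(replace(rf, mtry=max(int(np.sqrt(xt.shape[1])), 1)), xt.shape[1]).fit(xb, yb)

    pairs = oof[["p_bankR", "p_bankT"]].to_numpy(dtype=float)
    xb, yb = smote_balance(pairs, y, smote)
    # the 2-D risk-score space is small and noisy at these cohort sizes;
    # a minimum leaf size keeps the meta forest's surface smooth
    meta = RandomForestClassifier(
        n_estimators=rf.n_trees, max_features=2, min_samples_leaf=20,
        random_state=(rf.seed + 99) % (2 ** 31), n_jobs=1).fit(xb, yb)
    return RiskScoreBundle(model_r=model_r, model_t=model_t, meta_model=meta,
                           train_pairs=oof, columns_r=list(train_r.columns),
                           columns_t=list(train_t.columns))


def riskscore_predict(bundle: RiskScoreBundle, test_r: pd.DataFrame,
                      test_t: pd.DataFrame) -> np.ndarray:
    """Meta-model death probability for each test sample."""
    for cols, table, bank in ((bundle.columns_r, test_r, "R"), (bundle.columns_t, test_t, "T")):
        if list(table.columns) != cols:
            off = set(table.columns).symmetric_difference(cols)
            raise ValueError(f"bank {bank} column mismatch: {sorted(off)[:5]}")
    p_r = _death_proba(bundle.model_r, test_r.to_numpy(dtype=float))
    p_t = _death_proba(bundle.model_t, test_t.to_numpy(dtype=float))
    return _death_proba(bundle.meta_model, np.column_stack([p_r, p_t]))


# ---------------------------------------------------------------- benchmark

@dataclass(frozen=True)
class BenchmarkConfig:
    seed: int = 0
    folds: int = 10
    pca_var_threshold: float = 0.95
    boruta_max_iter: int = 100
    boruta_n_trees: int | None = None  # importance-forest size inside Boruta
    boruta_alpha: float = 0.05
    cox_alpha: float = 0.05
    lasso_corr_cutoff: float = 0.7
    n_trees: int = 500
    mtry_components: int = 2    # PCA / Boruta / LASSO / meta forests
    mtry_cox: int = 310         # Cox-pipeline forest
    smote: SmoteConfig = field(default_factory=SmoteConfig)


@dataclass
class BenchmarkResult:
    results: dict[str, FusionResult]
    table: pd.DataFrame
    single_bank_auc: dict[str, float] | None = None  # full-cohort bank models on test


METHODS = ("pca", "boruta", "cox", "lasso", "riskscore")


def _fit_selected(train: pd.DataFrame, test: pd.DataFrame, labels, selected: list[str],
                  rf: RFConfig, smote: SmoteConfig) -> np.ndarray:
    xb, yb = smote_balance(train[selected].to_numpy(dtype=float), labels, smote)
    model = _rf(rf, len(selected)).fit(xb, yb)
    return _death_proba(model, test[selected].to_numpy(dtype=float))


def run_benchmark(train_r, train_t, test_r, test_t, train_survival: pd.DataFrame,
                  test_labels, config: BenchmarkConfig = BenchmarkConfig()) -> BenchmarkResult:
    """Train all five pipelines on the training cohort, evaluate once on
    the test cohort, and compare the stacked model against each baseline
    with paired DeLong tests (BH-adjusted over the 4 comparisons).

    ``train_survival`` must carry time_days, event and a binary
    label_2yr for every training sample (90-day deaths already removed).
    """
    labels = train_survival["label_2yr"].to_numpy(dtype=int)
    y_test = np.asarray(test_labels).astype(int)
    rf_comp = RFConfig(n_trees=config.n_trees, mtry=config.mtry_components, seed=config.seed)
    rf_cox = RFConfig(n_trees=config.n_trees, mtry=config.mtry_cox, seed=config.seed)
    train_all = pd.concat([train_r, train_t], axis=1)
    test_all = pd.concat([test_r, test_t], axis=1)
    results: dict[str, FusionResult] = {}

    try:
        results["pca"] = fuse_pca(train_r, train_t, test_r, test_t, labels,
                                  config.pca_var_threshold, rf_comp, config.smote)

        selected = select_boruta(train_all, labels, config.boruta_max_iter,
                                 config.boruta_alpha, rf_comp, seed=config.seed,
                                 n_trees=config.boruta_n_trees)
        if not selected:
            # an all-noise cohort confirms nothing; keep the screen's best
            # single candidate so the pipeline still produces test scores
            imp = train_all.apply(lambda c: abs(np.corrcoef(c, labels)[0, 1]))
            selected = [imp.idxmax()]
            logger.warning("Boruta confirmed nothing; falling back to %s", selected[0])
        results["boruta"] = FusionResult(
            "boruta", selected,
            _fit_selected(train_all, test_all, labels, selected, rf_comp, config.smote))

        selected = select_univariate_cox(train_all, train_survival["time_days"],
                                         train_survival["event"], config.cox_alpha)
        if not selected:
            fits = {c: fit_univariate_cox(
                (train_all[c] - train_all[c].mean()) / train_all[c].std(),
                train_survival["time_days"], train_survival["event"]).p_value
                for c in train_all.columns if train_all[c].std() > 0}
            selected = [min(fits, key=fits.get)]
            logger.warning("Cox screen empty; falling back to %s", selected[0])
        results["cox"] = FusionResult(
            "cox", selected,
            _fit_selected(train_all, test_all, labels, selected, rf_cox, config.smote))

        selected = select_lasso(train_all, labels, config.lasso_corr_cutoff,
                                seed=config.seed)
        results["lasso"] = FusionResult(
            "lasso", selected,
            _fit_selected(train_all, test_all, labels, selected, rf_comp, config.smote))

        bundle = riskscore_fit(train_r, train_t, labels, config.folds, rf_comp,
                               config.smote, seed=config.seed)
        results["riskscore"] = FusionResult(
            "riskscore", ["p_bankR", "p_bankT"], riskscore_predict(bundle, test_r, test_t))
        single_bank = {
            "bankR": float(roc_auc(_death_proba(bundle.model_r, test_r.to_numpy(dtype=float)), y_test)),
            "bankT": float(roc_auc(_death_proba(bundle.model_t, test_t.to_numpy(dtype=float)), y_test)),
        }
    except Exception as exc:
        done = set(results)
        failed = next(m for m in METHODS if m not in done)
        raise RuntimeError(f"pipeline {failed!r} failed: {exc}") from exc

    rows = []
    p_values = {}
    for method in METHODS:
        res = results[method]
        res.auc_result = evaluate_scores(res.test_scores, y_test)
        if method != "riskscore":
            p_values[method] = delong_paired_test(
                results["riskscore"].test_scores, res.test_scores, y_test)
    adj = dict(zip(p_values, bh_adjust(list(p_values.values()))))
    for method in METHODS:
        a = results[method].auc_result
        rows.append({
            "method": method, "auc": a.auc, "ci_low": a.ci_low, "ci_high": a.ci_high,
            "youden_threshold": a.youden_threshold, "sensitivity": a.sensitivity,
            "specificity": a.specificity, "n_selected": len(results[method].selected),
            "delong_p_vs_riskscore": p_values.get(method, np.nan),
            "fdr_adjusted_p": adj.get(method, np.nan),
        })
    return BenchmarkResult(results=results, table=pd.DataFrame(rows).set_index("method"),
                           single_bank_auc=single_bank)
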