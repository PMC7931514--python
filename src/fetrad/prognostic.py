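"""Survival and recurrence-location modelling.

The prognostic stage mirrors the analysis design the pipeline implements:

1. univariate Kaplan-Meier screening — each candidate feature is split at
   the cohort median (ties to the low group) and the two groups compared
   with the log-rank test; the family threshold is Bonferroni alpha / K with
   K the number of features actually tested;
2. redundancy pruning — features that pass the univariate screen are grouped
   by strong Spearman correlation (p < 0.05 and |r| > 0.8, transitively);
   each group is represented by its member with the smallest log-rank p;
3. radiomics signature — the representatives enter a multivariate Cox
   proportional-hazards model (Efron ties); the signature risk score is the
   linear predictor beta' x, and the signature's Kaplan-Meier display splits
   the score at its median;
4. recurrence location — a logistic model on the chosen predictor, with
   imbalance-adjusted bootstrap resampling (equal expected class proportions
   per resample) for coefficient averaging and the 0.632+ estimator
   combining apparent and out-of-bag AUC / sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .screening import ScreeningConfig, spearman_strong_correlation

__all__ = [
    "KMResult",
    "SignatureModel",
    "RLModel",
    "km_logrank",
    "logrank_test",
    "bonferroni_threshold",
    "redundancy_groups",
    "fit_cox_signature",
    "cox_score_test",
    "fit_rl_model",
    "recurrence_location_label",
    "run_full_pipeline",
]


@dataclass(frozen=True)
class KMResult:
    feature: str
    n_low: int
    n_high: int
    chi2: float
    p: float
    split_value: float


@dataclass(frozen=True)
class SignatureModel:
    endpoint: str
    features: tuple[str, ...]
    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_likelihood_ratio: float
    p_wald: float
    p_score: float
    km_logrank_p: float  # median split of the risk score

    def risk_score(self, features: pd.DataFrame) -> np.ndarray:
        """The signature linear predictor beta' x."""
        lp = np.zeros(len(features))
        for name, b in self.coefficients.items():
            lp += b * features[name].to_numpy(float)
        return lp


@dataclass(frozen=True)
class RLModel:
    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # bootstrap-averaged, includes "intercept"
    n_boot: int
    seed: int
    auc: float
    sensitivity: float
    auc_apparent: float
    auc_oob: float
    threshold: float = 0.5


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank statistic and 1-df chi-square p value.

    Direct risk-table computation: at each distinct event time t, with n_g at
    risk and d_g events per group, O - E for group 1 accumulates
    d_1 - d n_1 / n and the hypergeometric variance
    d (n_1 / n)(1 - n_1 / n)(n - d)/(n - 1).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    t_events = np.unique(time[event])
    o_minus_e = 0.0
    var = 0.0
    for t in t_events:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        dead = event & (time == t)
        d = int(dead.sum())
        d1 = int((dead & group).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_logrank(values, time, event, feature_name: str = "") -> KMResult:
    """Median-split Kaplan-Meier comparison of one feature.

    Subjects with feature value <= median form the low group (ties go low).
    A degenerate split (constant feature) is an error.
    """
    values = np.asarray(values, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if values.size < 6:
        raise ValueError("need at least 6 subjects")
    med = float(np.median(values))
    high = values > med
    if high.all() or not high.any():
        raise ValueError(f"degenerate median split for feature {feature_name!r}")
    chi2, p = logrank_test(time, event, high)
    return KMResult(feature_name, int((~high).sum()), int(high.sum()), chi2, p, med)


def bonferroni_threshold(alpha: float, k: int) -> float:
    """The Bonferroni-corrected significance level alpha / K."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return alpha / k


def redundancy_groups(
    features: pd.DataFrame,
    km_results: dict[str, KMResult],
    cfg: ScreeningConfig = ScreeningConfig(),
) -> list[str]:
    """Pick one representative per correlated-feature group.

    Edges join features with strong Spearman correlation; connected
    components (transitive closure) form the groups; the representative is
    the member with the smallest log-rank p, ties broken by name order.
    """
    names = [n for n in features.columns if n in km_results]
    if not names:
        return []
    parent = {n: n for n in names}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            strong, _, _ = spearman_strong_correlation(
                features[a].to_numpy(), features[b].to_numpy(), cfg
            )
            if strong:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    reps = [
        min(members, key=lambda n: (km_results[n].p, n))
        for members in groups.values()
    ]
    return sorted(reps)


def cox_score_test(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Overall score (log-rank-type) test of beta = 0 for a Cox model.

    U' V^{-1} U with U and V the partial-likelihood score and information at
    beta = 0 (hypergeometric variance with the finite-population tie
    correction); chi-square with p = n_covariates degrees of freedom.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == len(time):
        x = x.T  # rows = covariates
    k = x.shape[0]
    u = np.zeros(k)
    v = np.zeros((k, k))
    t_events = np.unique(np.asarray(time, float)[np.asarray(event, bool)])
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    for t in t_events:
        risk = time >= t
        n = int(risk.sum())
        dead = event & (time == t)
        d = int(dead.sum())
        xr = x[:, risk]
        xbar = xr.mean(axis=1)
        u += x[:, dead].sum(axis=1) - d * xbar
        if n > 1:
            cov = (xr - xbar[:, None]) @ (xr - xbar[:, None]).T / n
            v += d * (n - d) / (n - 1) * cov
    try:
        chi2 = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        return float("nan")
    return float(stats.chi2.sf(chi2, df=k))


def fit_cox_signature(
    features: pd.DataFrame,
    time,
    event,
    endpoint: str = "ttp",
    alpha_ci: float = 0.05,
) -> SignatureModel:
    """Multivariate Cox fit of the selected features (Efron tie handling).

    Emits a warning (not an error) when events < 5 x covariates — small
    cohorts violate the usual comfort margin but must still be fittable.
    Reports coefficients, hazard ratios with 95% CI, the three overall tests
    (likelihood ratio, Wald, score) and the log-rank p of the median split of
    the risk score.
    """
    import warnings

    names = list(features.columns)
    df = features.copy()
    df["_time"] = np.asarray(time, float)
    df["_event"] = np.asarray(event, bool).astype(int)
    n_events = int(df["_event"].sum())
    if n_events < 5 * len(names):
        warnings.warn(
            f"{n_events} events for {len(names)} covariates: below the "
            "5-events-per-covariate comfort margin",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    beta = cph.params_.to_dict()
    se = cph.standard_errors_.to_dict()
    z = stats.norm.ppf(1 - alpha_ci / 2)
    b_vec = np.array([beta[n] for n in names])
    cov = cph.variance_matrix_.to_numpy()
    wald_chi2 = float(b_vec @ np.linalg.solve(cov, b_vec))
    p_wald = float(stats.chi2.sf(wald_chi2, df=len(names)))
    p_lr = float(cph.log_likelihood_ratio_test().p_value)
    p_score = cox_score_test(
        features.to_numpy(float), df["_time"].to_numpy(), df["_event"].to_numpy(bool)
    )
    risk = features.to_numpy(float) @ b_vec
    med = np.median(risk)
    high = risk > med
    if high.any() and not high.all():
        _, km_p = logrank_test(df["_time"], df["_event"].astype(bool), high)
    else:
        km_p = float("nan")
    return SignatureModel(
        endpoint=endpoint,
        features=tuple(names),
        coefficients={n: float(beta[n]) for n in names},
        hazard_ratios={n: float(np.exp(beta[n])) for n in names},
        ci_lower={n: float(np.exp(beta[n] - z * se[n])) for n in names},
        ci_upper={n: float(np.exp(beta[n] + z * se[n])) for n in names},
        p_likelihood_ratio=p_lr,
        p_wald=p_wald,
        p_score=p_score,
        km_logrank_p=float(km_p),
    )


def _sensitivity(y_true: np.ndarray, p_hat: np.ndarray, thr: float) -> float:
    pos = y_true == 1
    if not pos.any():
        return float("nan")
    return float((p_hat[pos] >= thr).mean())


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> LogisticRegression:
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    model.fit(x, y)
    return model


def fit_rl_model(
    predictors,
    rl_labels,
    n_boot: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    max_redraws: int = 50,
) -> RLModel:
    """Imbalance-adjusted bootstrap logistic model for recurrence location.

    Each bootstrap resample draws n subjects with the class chosen uniformly
    (equal expected class proportions) and the subject uniformly within the
    class — the imbalance adjustment. Coefficients are the mean over
    bootstrap fits. AUC and sensitivity are 0.632+ combinations of the
    apparent (full-data fit on full data) and out-of-bag performance; a
    resample whose out-of-bag set lacks a class is redrawn (bounded retries).
    """
    X = _as_matrix(predictors)
    y = np.asarray(rl_labels, float)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y[ok].astype(int)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 labelled subjects")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both recurrence-location classes must be present")
    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    full = _fit_logistic(X, y)
    p_full = full.predict_proba(X)[:, 1]
    auc_app = float(roc_auc_score(y, p_full))
    sens_app = _sensitivity(y, p_full, threshold)
    coefs = []
    oob_auc, oob_sens = [], []
    for _ in range(n_boot):
        idx0, idx1 = idx_by_class[classes[0]], idx_by_class[classes[1]]
        for _try in range(max_redraws):
            cls = rng.integers(0, 2, n)
            rows = np.where(
                cls == 0,
                idx0[rng.integers(idx0.size, size=n)],
                idx1[rng.integers(idx1.size, size=n)],
            )
            oob = np.setdiff1d(np.arange(n), rows)
            if np.unique(y[rows]).size == 2 and np.unique(y[oob]).size == 2:
                break
        else:
            continue
        m = _fit_logistic(X[rows], y[rows])
        coefs.append(np.concatenate([m.intercept_, m.coef_.ravel()]))
        p_oob = m.predict_proba(X[oob])[:, 1]
        oob_auc.append(roc_auc_score(y[oob], p_oob))
        oob_sens.append(_sensitivity(y[oob], p_oob, threshold))
    coefs = np.mean(coefs, axis=0)
    auc_oob = float(np.mean(oob_auc))
    sens_oob = float(np.nanmean(oob_sens))

    def point632plus(app: float, oob: float, null_level: float) -> float:
        if not np.isfinite(oob):
            return app
        oob_c = max(oob, null_level) if app > null_level else oob
        if app > null_level and oob_c < app:
            rel_overfit = (app - oob_c) / (app - null_level)
        else:
            rel_overfit = 0.0
        w = 0.632 / (1.0 - 0.368 * rel_overfit)
        return float((1.0 - w) * app + w * oob_c)

    names = list(predictors.columns) if isinstance(predictors, pd.DataFrame) else [
        f"x{i}" for i in range(X.shape[1])
    ]
    coef_map = {"intercept": float(coefs[0])}
    coef_map.update({nm: float(c) for nm, c in zip(names, coefs[1:])})
    return RLModel(
        predictors=tuple(names),
        coefficients=coef_map,
        n_boot=n_boot,
        seed=seed,
        auc=point632plus(auc_app, auc_oob, 0.5),
        sensitivity=point632plus(sens_app, sens_oob, 0.5),
        auc_apparent=auc_app,
        auc_oob=auc_oob,
        threshold=threshold,
    )


def _as_matrix(predictors) -> np.ndarray:
    if isinstance(predictors, pd.DataFrame):
        return predictors.to_numpy(float)
    arr = np.asarray(predictors, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def recurrence_location_label(recurrence_mask: np.ndarray, v_pet: np.ndarray) -> int:
    """1 when > 50% of the recurrence volume lies inside the initial v_pet."""
    n_rec = int(recurrence_mask.sum())
    if n_rec == 0:
        raise ValueError("empty recurrence volume")
    inside = int((recurrence_mask & v_pet).sum())
    return int(inside / n_rec > 0.5)


@dataclass
class PipelineResult:
    km_table: pd.DataFrame
    bonferroni_k: int
    bonferroni_alpha: float
    significant_features: list[str]
    representatives_ttp: list[str]
    representatives_os: list[str]
    signature_ttp: SignatureModel | None
    signature_os: SignatureModel | None
    rl_signature: RLModel | None
    rl_best_feature: RLModel | None
    best_feature_ttp: str | None


def run_full_pipeline(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    robust_features: list[str] | None = None,
    cfg: ScreeningConfig = ScreeningConfig(),
    n_boot: int = 1000,
    seed: int = 0,
) -> PipelineResult:
    """Univariate screen -> redundancy pruning -> Cox signatures -> RL model.

    ``features``: one row per subject, feature columns. ``outcomes``: columns
    ttp_days, ttp_event, os_days, os_event, rl_label (NaN where undefined).
    ``robust_features`` restricts the candidate set (scanner-robust features
    from phantom screening); None admits every column.
    """
    if len(features) != len(outcomes):
        raise ValueError("feature and outcome tables must align per subject")
    cand = [c for c in features.columns if robust_features is None or c in robust_features]
    km: dict[str, dict[str, KMResult]] = {"ttp": {}, "os": {}}
    rows = []
    for name in cand:
        vals = features[name].to_numpy(float)
        if not np.all(np.isfinite(vals)) or np.unique(vals).size < 2:
            continue  # undefined or constant features cannot be split
        row = {"feature": name}
        for ep in ("ttp", "os"):
            res = km_logrank(
                vals, outcomes[f"{ep}_days"], outcomes[f"{ep}_event"], name
            )
            km[ep][name] = res
            row[f"p_{ep}"] = res.p
        rows.append(row)
    km_table = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["p_ttp", "p_os"]
    )
    k = len(km_table)
    thr = bonferroni_threshold(cfg.alpha, max(k, 1))
    significant = sorted(
        km_table.index[(km_table["p_ttp"] < thr) | (km_table["p_os"] < thr)]
    ) if k else []

    signatures: dict[str, SignatureModel | None] = {}
    reps_by_ep: dict[str, list[str]] = {}
    for ep in ("ttp", "os"):
        cand_ep = {n: r for n, r in km[ep].items() if r.p < cfg.alpha}
        reps = redundancy_groups(features[list(cand_ep)], cand_ep, cfg) if cand_ep else []
        reps_by_ep[ep] = reps
        if reps:
            signatures[ep] = fit_cox_signature(
                features[reps], outcomes[f"{ep}_days"], outcomes[f"{ep}_event"], ep
            )
        else:
            signatures[ep] = None

    rl_sig = rl_best = None
    best_feature = None
    has_rl = outcomes["rl_label"].notna().sum() >= 10 and (
        outcomes["rl_label"].dropna().nunique() == 2
    )
    if km["ttp"]:
        best_feature = min(km["ttp"], key=lambda n: (km["ttp"][n].p, n))
    if has_rl:
        y = outcomes["rl_label"].to_numpy(float)
        if signatures["ttp"] is not None:
            score = signatures["ttp"].risk_score(features)
            rl_sig = fit_rl_model(
                pd.DataFrame({"ttp_signature_score": score}), y, n_boot, seed
            )
        if best_feature is not None:
            rl_best = fit_rl_model(
                features[[best_feature]], y, n_boot, seed + 1
            )
    return PipelineResult(
        km_table=km_table,
        bonferroni_k=k,
        bonferroni_alpha=thr,
        significant_features=significant,
        representatives_ttp=reps_by_ep["ttp"],
        representatives_os=reps_by_ep["os"],
        signature_ttp=signatures["ttp"],
        signature_os=signatures["os"],
        rl_signature=rl_sig,
        rl_best_feature=rl_best,
        best_feature_ttp=best_feature,
    )
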