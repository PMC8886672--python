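"""Clinical evaluation of biomarkers and subtypes.

Per-biomarker proportional-hazards screening with Benjamini–Hochberg FDR,
high/low dichotomization (maximally selected log-rank statistic or median
split) with Kaplan–Meier curves, multivariable Cox modelling with backward
AIC selection, bootstrap-cross-validated logistic classification of binary
outcomes, and horizon-specific survival-AUC comparison of nested models.

Model fitting is delegated to lifelines (Cox partial likelihood with Efron
tie handling, Kaplan–Meier, log-rank) and statsmodels (logistic MLE,
multiple-testing correction); the screening, cutpoint-search and bootstrap
harnesses are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class HazardResult:
    """One covariate's proportional-hazards summary."""

    name: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    q: float | None = None
    coef: float = np.nan

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")


@dataclass
class ClassifierEval:
    """Bootstrap-cross-validated classifier performance."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_boot: int
    train_frac: float
    resampled_splits: int = 0
    per_iteration: pd.DataFrame | None = field(default=None, repr=False)


def _check_survival(surv: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in surv.columns:
            raise ValueError(f"survival table must have a {col!r} column")
    if (surv["time"] < 0).any():
        raise ValueError("times must be nonnegative")
    if surv["sample_id"].duplicated().any() if "sample_id" in surv.columns else False:
        raise ValueError("duplicate sample_ids in survival table")
    return surv


def cox_univariate(feature: np.ndarray, surv: pd.DataFrame, name: str = "x") -> HazardResult:
    """Single-covariate Cox proportional-hazards fit (Efron ties).

    Returns the hazard ratio per unit of ``feature`` with Wald 95% CI and p.
    Degenerate inputs (fewer than 2 events, constant feature) raise rather
    than silently returning a null effect.
    """
    surv = _check_survival(surv)
    x = np.asarray(feature, dtype=float)
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events for a proportional-hazards fit")
    if np.ptp(x) <= 0:
        raise ValueError(f"feature {name!r} is constant")
    df = pd.DataFrame({"time": surv["time"].to_numpy(float),
                       "event": surv["event"].to_numpy(int), name: x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event",
            fit_options={"precision": 1e-12})
    s = cph.summary.loc[name]
    return HazardResult(
        name=name,
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p=float(s["p"]),
        coef=float(s["coef"]),
    )


def screen_biomarkers(contexts: pd.DataFrame, surv: pd.DataFrame) -> pd.DataFrame:
    """Univariate hazard screen of every biomarker column, FDR-adjusted.

    Constant biomarkers are reported with NaN statistics (never a silent
    HR of 1). Returns one row per column with HR, CI, p and BH q.
    """
    rows = []
    for col in contexts.columns:
        x = contexts[col].to_numpy(float)
        if np.ptp(x) <= 0:
            rows.append({"biomarker": col, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan})
            continue
        r = cox_univariate(x, surv, name=str(col))
        rows.append({"biomarker": col, "hr": r.hr, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "p": r.p})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    return out


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def dichotomize(
    feature: np.ndarray,
    surv: pd.DataFrame,
    method: str = "maxrank",
    min_group: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Split samples into high/low groups on a biomarker.

    ``maxrank`` scans candidate cutpoints (midpoints between consecutive
    unique values keeping both groups at ``min_group`` of the cohort) and
    picks the one maximizing the log-rank chi-square between the groups.
    ``median`` splits at the median. Returns string labels
    (``"high"``/``"low"``, high means strictly above the cutpoint) and the
    cutpoint.
    """
    surv = _check_survival(surv)
    x = np.asarray(feature, dtype=float)
    n = len(x)
    if np.ptp(x) <= 0:
        raise ValueError("feature has no variation; cannot dichotomize")
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)

    if method == "median":
        cut = float(np.median(x))
        labels = np.where(x > cut, "high", "low")
        if len(np.unique(labels)) < 2:
            raise ValueError("median split produced a single group")
        return labels, cut
    if method != "maxrank":
        raise ValueError(f"unknown method {method!r}")

    min_n = max(int(np.ceil(min_group * n)), 1)
    order = np.sort(np.unique(x))
    cuts = (order[:-1] + order[1:]) / 2
    best_stat, best_cut = -np.inf, None
    for cut in cuts:
        high = x > cut
        n_high = int(high.sum())
        if n_high < min_n or n - n_high < min_n:
            continue
        res = logrank_test(time[high], time[~high], event[high], event[~high])
        if res.test_statistic > best_stat:
            best_stat, best_cut = float(res.test_statistic), float(cut)
    if best_cut is None:
        raise ValueError("no admissible cutpoint under the group-size constraint")
    return np.where(x > best_cut, "high", "low"), best_cut


def km_logrank(
    groups: np.ndarray, surv: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per group plus the log-rank test across groups.

    Returns (curves, chi-square statistic, p). Each curve is a DataFrame with
    ``time`` and ``survival`` columns (product-limit estimate).
    """
    surv = _check_survival(surv)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank comparison needs at least 2 groups")
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    curves = {}
    for g in uniq:
        sel = groups == g
        if not sel.any():
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    test = multivariate_logrank_test(time, groups, event)
    return curves, float(test.test_statistic), float(test.p_value)


def _design(surv: pd.DataFrame, candidates: list[str]) -> pd.DataFrame:
    """Expand categorical candidates into dummy columns (first level dropped)."""
    cols = {}
    for name in candidates:
        if name not in surv.columns:
            raise ValueError(f"covariate {name!r} not in table")
        col = surv[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[name] = col.to_numpy(float)
    return pd.DataFrame(cols, index=surv.index)


def _check_collinear(X: pd.DataFrame) -> None:
    Z = (X - X.mean()) / X.std().replace(0, 1)
    if Z.shape[1] < 2:
        return
    cond = np.linalg.cond(Z.to_numpy(float))
    if cond > 1e8:
        corr = Z.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        raise ValueError(
            f"collinear covariates (condition number {cond:.3g}): "
            f"{X.columns[i]!r} vs {X.columns[j]!r}"
        )


def cox_multivariable(
    surv: pd.DataFrame,
    candidates: list[str],
    selection: str = "none",
    alpha_enter: float = 0.05,
) -> tuple[CoxPHFitter, list[HazardResult]]:
    """Multivariable Cox model, optionally with stepwise selection.

    ``selection="none"`` fits all candidates simultaneously.
    ``selection="stepwise_aic"`` starts from the candidates that are
    univariately significant (p < ``alpha_enter``) and backward-eliminates by
    AIC until no single removal improves it. Categorical covariates are
    dummy-expanded. Returns the fitted model and adjusted hazard results for
    the retained design columns.
    """
    surv = _check_survival(surv)
    X = _design(surv, list(candidates))
    _check_collinear(X)
    base = pd.DataFrame(
        {"time": surv["time"].to_numpy(float), "event": surv["event"].to_numpy(int)},
        index=surv.index,
    )

    def fit(cols: list[str]) -> CoxPHFitter:
        cph = CoxPHFitter()
        cph.fit(pd.concat([base, X[cols]], axis=1), "time", "event",
                fit_options={"precision": 1e-12})
        return cph

    cols = list(X.columns)
    if selection == "stepwise_aic":
        keep = []
        for c in cols:
            r = cox_univariate(X[c].to_numpy(), surv, name=c)
            if r.p < alpha_enter:
                keep.append(c)
        if not keep:
            raise ValueError("no univariately significant candidates to select from")
        model = fit(keep)
        improved = True
        while improved and len(keep) > 1:
            improved = False
            current_aic = model.AIC_partial_
            for c in list(keep):
                trial = [x for x in keep if x != c]
                m2 = fit(trial)
                if m2.AIC_partial_ < current_aic:
                    keep, model, current_aic = trial, m2, m2.AIC_partial_
                    improved = True
        cols = keep
    elif selection == "none":
        model = fit(cols)
    else:
        raise ValueError(f"unknown selection {selection!r}")

    results = []
    for c in cols:
        s = model.summary.loc[c]
        results.append(
            HazardResult(
                name=c,
                hr=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p=float(s["p"]),
                coef=float(s["coef"]),
            )
        )
    qs = fdr_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    return model, results


def bootstrap_classifier_eval(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    train_frac: float = 0.6,
    n_boot: int = 100,
    seed: int = 0,
) -> ClassifierEval:
    """Bootstrap-cross-validated logistic classification.

    Per iteration: stratified train/test split (``train_frac`` for training),
    logistic fit on the training part, AUC by rank statistic on the test
    part, sensitivity/specificity at the Youden-optimal threshold chosen on
    the training scores. Reports medians and percentile 95% CIs across
    iterations. Splits missing a class are redrawn (counted in
    ``resampled_splits``).
    """
    from sklearn.linear_model import LogisticRegression

    X = features.to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    rows = []
    resampled = 0
    for _ in range(n_boot):
        for _retry in range(100):
            split_seed = int(rng.integers(0, 2**31 - 1))
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=train_frac, stratify=y, random_state=split_seed
            )
            if len(np.unique(ytr)) == 2 and len(np.unique(yte)) == 2:
                break
            resampled += 1
        clf = LogisticRegression(C=np.inf, max_iter=1000)  # unpenalized MLE
        clf.fit(Xtr, ytr)
        score_tr = clf.decision_function(Xtr)
        score_te = clf.decision_function(Xte)
        auc = roc_auc_score(yte, score_te)
        fpr, tpr, thresholds = roc_curve(ytr, score_tr)
        thr = thresholds[np.argmax(tpr - fpr)]
        pred = score_te >= thr
        sens = float(pred[yte == 1].mean())
        spec = float((~pred[yte == 0]).mean())
        rows.append({"auc": float(auc), "sensitivity": sens, "specificity": spec})
    if resampled:
        logger.info("redrew %d degenerate splits", resampled)
    per = pd.DataFrame(rows)

    def ci(col: str) -> tuple[float, float]:
        lo, hi = np.percentile(per[col], [2.5, 97.5])
        return float(lo), float(hi)

    return ClassifierEval(
        auc=float(per["auc"].median()),
        auc_ci=ci("auc"),
        sensitivity=float(per["sensitivity"].median()),
        sensitivity_ci=ci("sensitivity"),
        specificity=float(per["specificity"].median()),
        specificity_ci=ci("specificity"),
        n_boot=n_boot,
        train_frac=train_frac,
        resampled_splits=resampled,
        per_iteration=per,
    )


def _horizon_auc(lp: np.ndarray, time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Cumulative/dynamic AUC at a horizon from a risk score.

    Cases: event observed by the horizon; controls: still at risk past it.
    Censored-before-horizon subjects are excluded. NaN when either set is
    empty in the resample.
    """
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        return np.nan
    sel = cases | controls
    return float(roc_auc_score(cases[sel].astype(int), lp[sel]))


def survival_auc_compare(
    surv: pd.DataFrame,
    covariates_full: list[str],
    covariates_reduced: list[str],
    horizons: list[float],
    n_boot: int = 1000,
    rate: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare nested Cox models by horizon-specific survival AUC.

    Per bootstrap resample (fraction ``rate`` without replacement) both
    models are refit, and the cumulative/dynamic AUC of their linear
    predictors is computed out-of-bag on the held-out fraction (in-sample
    evaluation would inflate a noise model above chance by fitting
    optimism). The paired two-sided p doubles the fraction of resamples
    where the full model does not beat the reduced one, floored at
    1/n_boot. Returns one row per horizon.
    """
    surv = _check_survival(surv).reset_index(drop=True)
    if not set(covariates_reduced) <= set(covariates_full):
        raise ValueError("reduced covariates must be a subset of the full set")
    tmax = surv.loc[surv["event"] == 1, "time"].max() if (surv["event"] == 1).any() else surv["time"].max()
    for h in horizons:
        if h > surv["time"].max():
            raise ValueError(f"horizon {h} beyond observed follow-up {tmax:.3g}")
    n = len(surv)
    m = int(np.ceil(rate * n))
    rng = np.random.default_rng(seed)

    X_full = _design(surv, list(covariates_full))
    X_red = _design(surv, list(covariates_reduced))
    base = pd.DataFrame(
        {"time": surv["time"].to_numpy(float), "event": surv["event"].to_numpy(int)}
    )

    auc_full = np.full((n_boot, len(horizons)), np.nan)
    auc_red = np.full((n_boot, len(horizons)), np.nan)
    for b in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        oob = np.setdiff1d(np.arange(n), idx)
        sub_base = base.iloc[idx].reset_index(drop=True)
        time_o = base["time"].to_numpy()[oob]
        event_o = base["event"].to_numpy()[oob]
        lps = []
        for Xd in (X_full, X_red):
            df = pd.concat([sub_base, Xd.iloc[idx].reset_index(drop=True)], axis=1)
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, "time", "event")
            lps.append(
                cph.predict_partial_hazard(Xd.iloc[oob].reset_index(drop=True)).to_numpy(float)
            )
        for hi, h in enumerate(horizons):
            auc_full[b, hi] = _horizon_auc(lps[0], time_o, event_o, h)
            auc_red[b, hi] = _horizon_auc(lps[1], time_o, event_o, h)

    rows = []
    for hi, h in enumerate(horizons):
        af, ar = auc_full[:, hi], auc_red[:, hi]
        ok = ~(np.isnan(af) | np.isnan(ar))
        one_sided = float((af[ok] <= ar[ok]).mean()) if ok.any() else np.nan
        p = max(min(2 * one_sided, 1.0), 1.0 / n_boot)
        rows.append(
            {
                "horizon": h,
                "auc_full": float(np.nanmean(af)),
                "auc_reduced": float(np.nanmean(ar)),
                "delta": float(np.nanmean(af - ar)),
                "p": p,
                "n_boot_used": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
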