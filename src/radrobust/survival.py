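"""ICC-guided feature selection, Cox survival modelling, and generalizability.

The modelling cascade mirrors the databank's intended use: (1) keep features
whose mean ICC exceeds a repeatability threshold (shape features are excluded
from the modelling pool — models use first-/high-order features only),
(2) univariate Cox screening at p < 0.05, (3) bootstrap-stabilized LASSO-Cox
selection ranked by how often each feature gets a non-zero coefficient,
(4) a multivariate Cox model on the top-k (default 5) features.

Performance is Harrell's concordance (C) index with bootstrap CIs, and
transportability is the generalizability index

    G = (1/M) * sum_m | C_train - C_EV_m |

over M external-validation cohorts; lower G means the model travels better.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.base import BaseEstimator
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

__all__ = [
    "SurvivalDataset",
    "SelectionTrace",
    "GeneralizabilityReport",
    "CoxRiskModel",
    "UnivariateCoxSelector",
    "LassoFrequencySelector",
    "preselect_by_icc",
    "univariate_screen",
    "lasso_frequency_select",
    "fit_final_model",
    "c_index",
    "bootstrap_c",
    "g_index",
    "run_threshold_experiment",
    "feature_number_sweep",
]


@dataclass
class SurvivalDataset:
    """Feature table plus (time, event) outcomes for one cohort."""

    cohort_name: str
    features: pd.DataFrame
    outcomes: pd.DataFrame  # columns: time, event

    def __post_init__(self) -> None:
        if not {"time", "event"} <= set(self.outcomes.columns):
            raise ValueError("outcomes must have 'time' and 'event' columns")
        if len(self.features) != len(self.outcomes):
            raise ValueError("features and outcomes must cover the same patients")
        if self.outcomes[["time", "event"]].isna().any(axis=None):
            raise ValueError("missing outcomes are not allowed")
        if (self.outcomes["time"] <= 0).any():
            raise ValueError("follow-up times must be positive")

    @property
    def n_events(self) -> int:
        return int(self.outcomes["event"].sum())

    def subset(self, idx) -> "SurvivalDataset":
        return SurvivalDataset(
            self.cohort_name,
            self.features.iloc[idx].reset_index(drop=True),
            self.outcomes.iloc[idx].reset_index(drop=True),
        )


@dataclass
class SelectionTrace:
    """Record of which features survived each selection stage."""

    icc_threshold: float | None
    survivors_after_icc: list[str]
    survivors_after_univariate: list[str]
    bootstrap_selections: list[list[str]] = field(default_factory=list)
    frequency: dict[str, int] = field(default_factory=dict)
    final_features: list[str] = field(default_factory=list)


@dataclass
class GeneralizabilityReport:
    """C indices (mean and 95% CI) per cohort plus the G index."""

    icc_threshold: float | None
    n_features: int
    features: list[str]
    c_train: tuple[float, float, float]
    c_test: tuple[float, float, float] | None
    c_ev: dict[str, tuple[float, float, float]]
    g_mean: float
    g_ci: tuple[float, float]
    trace: SelectionTrace | None = None


# ---------------------------------------------------------------------------
# selection stages
# ---------------------------------------------------------------------------

def preselect_by_icc(
    databank: pd.DataFrame, threshold: float | None
) -> list[str]:
    """Features whose mean ICC strictly exceeds ``threshold``.

    ``threshold`` of None (or "none") keeps every non-degenerate feature.
    Shape features are always excluded from the modelling pool.
    """
    df = databank[databank["family"] != "shape"]
    df = df[df["class_label"] != "degenerate"]
    if threshold is None or (isinstance(threshold, str) and threshold == "none"):
        return df.index.tolist()
    return df[df["mean_icc"] > float(threshold)].index.tolist()


def _surv_y(outcomes: pd.DataFrame):
    return Surv.from_arrays(
        event=outcomes["event"].astype(bool).to_numpy(),
        time=outcomes["time"].to_numpy(dtype=float),
    )


def univariate_screen(
    ds: SurvivalDataset, candidates: list[str], alpha: float = 0.05
) -> list[str]:
    """Single-covariate Cox fits; keep features with Wald p below ``alpha``.

    Features are z-scored before fitting so hazard ratios are per standard
    deviation; features whose fit fails to converge are dropped with a
    warning.
    """
    if ds.n_events < 10:
        raise ValueError(f"need >= 10 events for screening, got {ds.n_events}")
    kept = []
    for name in candidates:
        col = ds.features[name].to_numpy(dtype=float)
        sd = col.std()
        if not np.isfinite(sd) or sd == 0:
            continue
        df = pd.DataFrame(
            {
                "time": ds.outcomes["time"].to_numpy(),
                "event": ds.outcomes["event"].to_numpy(),
                "x": (col - col.mean()) / sd,
            }
        )
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"univariate Cox failed for {name!r}: {exc}", stacklevel=2)
            continue
        if float(cph.summary.loc["x", "p"]) < alpha:
            kept.append(name)
    return kept


def _coxnet_selected(
    X: np.ndarray, y, feature_names: list[str], cv_folds: int, rng: np.random.Generator
) -> list[str]:
    """Non-zero-coefficient features of an L1 Cox fit at a CV-chosen penalty."""
    base = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=30, alpha_min_ratio=0.01, max_iter=100000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base.fit(X, y)
    alphas = np.asarray(base.alphas_)

    n = X.shape[0]
    order = rng.permutation(n)
    folds = np.array_split(order, cv_folds)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for i in range(cv_folds):
        test_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(cv_folds) if j != i])
        if y[train_idx]["event"].sum() < 3 or y[test_idx]["event"].sum() < 1:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, max_iter=100000)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X[train_idx], y[train_idx])
        except (ValueError, ArithmeticError):
            continue
        for a_i, alpha in enumerate(m.alphas_):
            pred = m.predict(X[test_idx], alpha=alpha)
            ev = y[test_idx]["event"]
            tm = y[test_idx]["time"]
            try:
                ci = concordance_index_censored(ev, tm, pred)[0]
            except (ValueError, ZeroDivisionError):
                continue
            scores[a_i] += ci
            counts[a_i] += 1
    with np.errstate(invalid="ignore"):
        mean_scores = np.where(counts > 0, scores / np.maximum(counts, 1), -np.inf)
    best = int(np.argmax(mean_scores)) if np.isfinite(mean_scores).any() else len(alphas) // 2
    coefs = base.coef_[:, best] if base.coef_.ndim == 2 else base.coef_
    return [feature_names[j] for j in np.flatnonzero(np.abs(coefs) > 1e-10)]


def lasso_frequency_select(
    ds: SurvivalDataset,
    candidates: list[str],
    n_bootstraps: int = 10,
    k: int = 5,
    seed: int = 0,
    cv_folds: int = 3,
) -> tuple[list[str], SelectionTrace]:
    """Bootstrap-stabilized LASSO-Cox selection.

    Per bootstrap: resample patients with replacement, z-score on the
    resample, fit an L1-penalized Cox model with the penalty chosen by
    internal cross-validated concordance, and record the features with
    non-zero coefficients. Features are ranked by selection frequency (ties
    broken lexicographically) and the top ``k`` returned.
    """
    if not candidates:
        raise ValueError("no candidate features for LASSO selection")
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ds.features)
    selections: list[list[str]] = []
    for _ in range(n_bootstraps):
        idx = rng.integers(0, n, size=n)
        sub = ds.subset(idx)
        X = sub.features[candidates].to_numpy(dtype=float)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.any() or sub.n_events < 5:
            selections.append([])
            continue
        Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        names = [c for c, k_ in zip(candidates, keep) if k_]
        y = _surv_y(sub.outcomes)
        try:
            sel = _coxnet_selected(Xz, y, names, cv_folds, rng)
        except (ValueError, ArithmeticError) as exc:
            warnings.warn(f"LASSO bootstrap failed: {exc}", stacklevel=2)
            sel = []
        selections.append(sel)

    freq: dict[str, int] = {}
    for sel in selections:
        for name in sel:
            freq[name] = freq.get(name, 0) + 1
    if not freq:
        raise ValueError("LASSO selected no features in any bootstrap")
    ranked = sorted(freq, key=lambda f: (-freq[f], f))
    top = ranked[: min(k, len(ranked))]
    if len(top) < k:
        warnings.warn(
            f"only {len(top)} features were ever selected (requested {k})",
            stacklevel=2,
        )
    trace = SelectionTrace(
        icc_threshold=None,
        survivors_after_icc=list(candidates),
        survivors_after_univariate=list(candidates),
        bootstrap_selections=selections,
        frequency=freq,
        final_features=top,
    )
    return top, trace


# ---------------------------------------------------------------------------
# modelling and evaluation
# ---------------------------------------------------------------------------

class CoxRiskModel(BaseEstimator):
    """Multivariate Cox proportional-hazards risk model.

    Features are z-scored with statistics learned on the training cohort and
    reused verbatim on every evaluation cohort. Collinear designs are refit
    with a small ridge penalty (with a warning). ``predict`` returns the
    linear predictor (log partial hazard); ``score`` is Harrell's C.
    """

    def __init__(self, features: list[str] | None = None, penalizer: float = 0.0):
        self.features = features
        self.penalizer = penalizer

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        names = list(self.features) if self.features else list(X.columns)
        if not names:
            raise ValueError("no features to fit")
        missing = set(names) - set(X.columns)
        if missing:
            raise KeyError(f"features not in table: {sorted(missing)}")
        F = X[names].to_numpy(dtype=float)
        self.mean_ = F.mean(axis=0)
        sd = F.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (F - self.mean_) / self.scale_
        # constant features carry no information: fixed at coefficient zero
        active = [n for n, s in zip(names, sd) if s > 0]
        df = pd.DataFrame(Z[:, sd > 0], columns=active)
        df["time"] = y["time"].to_numpy(dtype=float)
        df["event"] = y["event"].to_numpy(dtype=int)
        coef = pd.Series(0.0, index=names)
        fitter = None
        if active:
            fitter = CoxPHFitter(penalizer=self.penalizer)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fitter.fit(df, duration_col="time", event_col="event")
            except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(
                    f"Cox fit unstable ({exc}); refitting with ridge penalty 0.1",
                    stacklevel=2,
                )
                fitter = CoxPHFitter(penalizer=0.1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fitter.fit(df, duration_col="time", event_col="event")
            coef[active] = fitter.params_[active].to_numpy()
        self.feature_names_ = names
        self.model_ = fitter
        self.coef_ = coef.to_numpy()
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.feature_names_].to_numpy(dtype=float) - self.mean_) / self.scale_
        return Z @ self.coef_

    def score(self, X: pd.DataFrame, y: pd.DataFrame) -> float:
        return _harrell_c(
            y["time"].to_numpy(float), y["event"].to_numpy(int), self.predict(X)
        )


def fit_final_model(ds_train: SurvivalDataset, names: list[str]) -> CoxRiskModel:
    """Fit the multivariate Cox model on standardized training features."""
    if not names:
        raise ValueError("empty feature selection at modelling time")
    return CoxRiskModel(features=list(names)).fit(ds_train.features, ds_train.outcomes)


def _harrell_c(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> float:
    """Harrell's concordance of risk scores with observed survival."""
    c, _, _, _, _ = concordance_index_censored(
        event.astype(bool), time.astype(float), np.asarray(risk, dtype=float)
    )
    return float(c)


def c_index(model: CoxRiskModel, ds: SurvivalDataset) -> float:
    """Harrell's C of a fitted risk model on a cohort (ties count 0.5)."""
    return model.score(ds.features, ds.outcomes)


def bootstrap_c(
    model: CoxRiskModel, ds: SurvivalDataset, n_boot: int = 100, seed: int = 0
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Patient-level bootstrap of the evaluation cohort's C index.

    Returns (mean, (2.5%, 97.5%) percentile CI, the bootstrap samples). The
    model is fixed; only the evaluation cohort is resampled.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    n = len(ds.features)
    if n < 2:
        raise ValueError("cohort too small to bootstrap")
    rng = np.random.default_rng(seed)
    risk = model.predict(ds.features)
    time = ds.outcomes["time"].to_numpy(float)
    event = ds.outcomes["event"].to_numpy(int)
    samples = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() == 0:
            idx = np.arange(n)
        samples[b] = _harrell_c(time[idx], event[idx], risk[idx])
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return float(samples.mean()), (float(lo), float(hi)), samples


def g_index(c_train: float, c_evs: list[float]) -> float:
    """Mean absolute gap between the training C and each EV cohort's C."""
    if len(c_evs) == 0:
        raise ValueError("need at least one EV cohort")
    return float(np.mean([abs(c_train - c) for c in c_evs]))


def run_threshold_experiment(
    databank: pd.DataFrame,
    train: SurvivalDataset,
    evs: list[SurvivalDataset],
    test: SurvivalDataset | None = None,
    thresholds: tuple[float | None, ...] = (0.9, 0.85, 0.8, 0.75, 0.5, None),
    n_bootstraps: int = 10,
    k: int = 5,
    n_boot_eval: int = 100,
    seed: int = 0,
    screen_alpha: float = 0.05,
) -> dict[float | None, GeneralizabilityReport]:
    """Run the full selection + modelling cascade at each ICC threshold.

    Per threshold: ICC preselection -> univariate screen on the training
    cohort -> bootstrap LASSO frequency top-k -> multivariate Cox ->
    bootstrapped C on every cohort -> G over the EV cohorts (mean and
    percentile CI over paired bootstrap replicates).
    """
    if not evs:
        raise ValueError("need at least one EV cohort")
    reports: dict[float | None, GeneralizabilityReport] = {}
    for t_i, thr in enumerate(thresholds):
        pool = preselect_by_icc(databank, thr)
        pool = [f for f in pool if f in train.features.columns]
        if not pool:
            raise ValueError(f"ICC threshold {thr} leaves no candidate features")
        screened = univariate_screen(train, pool, alpha=screen_alpha)
        if not screened:
            raise ValueError(
                f"univariate screening left no features at threshold {thr}"
            )
        if len(screened) > k:
            final, trace = lasso_frequency_select(
                train, screened, n_bootstraps=n_bootstraps, k=k,
                seed=seed * 1000 + t_i,
            )
        else:
            final = screened
            trace = SelectionTrace(thr, pool, screened, final_features=final)
        trace.icc_threshold = thr
        trace.survivors_after_icc = pool
        trace.survivors_after_univariate = screened

        model = fit_final_model(train, final)
        ct_mean, ct_ci, ct_samp = bootstrap_c(model, train, n_boot_eval, seed + 1)
        c_test_summary = None
        if test is not None:
            m, ci, _ = bootstrap_c(model, test, n_boot_eval, seed + 2)
            c_test_summary = (m, *ci)
        c_ev_summary: dict[str, tuple[float, float, float]] = {}
        ev_samps = []
        for j, ev in enumerate(evs):
            m, ci, samp = bootstrap_c(model, ev, n_boot_eval, seed + 3 + j)
            c_ev_summary[ev.cohort_name] = (m, *ci)
            ev_samps.append(samp)
        g_samples = np.mean(
            [np.abs(ct_samp - s) for s in ev_samps], axis=0
        )
        g_lo, g_hi = np.percentile(g_samples, [2.5, 97.5])
        reports[thr] = GeneralizabilityReport(
            icc_threshold=thr,
            n_features=len(final),
            features=final,
            c_train=(ct_mean, *ct_ci),
            c_test=c_test_summary,
            c_ev=c_ev_summary,
            g_mean=g_index(ct_mean, [v[0] for v in c_ev_summary.values()]),
            g_ci=(float(g_lo), float(g_hi)),
            trace=trace,
        )
    return reports


def feature_number_sweep(
    ds_train: SurvivalDataset,
    ds_test: SurvivalDataset,
    candidates: list[str],
    k_range: range | list[int] = range(1, 11),
    n_bootstraps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/test C as a function of the number of modelled features.

    Features are ranked once by bootstrap LASSO frequency; for each k the
    top-k model is fitted and train/test C and their gap recorded.
    """
    ranked, _ = lasso_frequency_select(
        ds_train, candidates, n_bootstraps=n_bootstraps, k=len(candidates), seed=seed
    )
    rows = []
    for k in k_range:
        if k > len(ranked):
            break
        model = fit_final_model(ds_train, ranked[:k])
        ct = c_index(model, ds_train)
        cv = c_index(model, ds_test)
        rows.append((k, ct, cv, ct - cv))
    return pd.DataFrame(rows, columns=["k", "c_train", "c_test", "gap"])


class UnivariateCoxSelector(BaseEstimator):
    """Estimator wrapper around :func:`univariate_screen`."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        ds = SurvivalDataset("train", X.reset_index(drop=True), y.reset_index(drop=True))
        self.selected_features_ = univariate_screen(ds, list(X.columns), self.alpha)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]


class LassoFrequencySelector(BaseEstimator):
    """Estimator wrapper around :func:`lasso_frequency_select`."""

    def __init__(self, n_bootstraps: int = 10, k: int = 5, seed: int = 0):
        self.n_bootstraps = n_bootstraps
        self.k = k
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        ds = SurvivalDataset("train", X.reset_index(drop=True), y.reset_index(drop=True))
        self.selected_features_, self.trace_ = lasso_frequency_select(
            ds, list(X.columns), self.n_bootstraps, self.k, self.seed
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]
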