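"""Feature repeatability scoring: one-way ICC, resampled CIs, and the databank.

Each feature is measured once per (patient, perturbation) and arranged as an
n_patients x k matrix (column 0 unperturbed, the rest perturbed). Because
perturbation parameters are assigned independently of patients, repeatability
is quantified by the one-way random-effects, absolute-agreement,
single-measurement ICC:

    ICC(1,1) = (MSn - MSW) / (MSn + (k - 1) MSW)

with MSn the between-patient and MSW the within-patient mean square. The
``paper_literal`` variant replaces (k - 1) with (k + 1), preserving a printed
variant of the estimator. Repeatability classes: poor (< 0.5), moderate
[0.5, 0.75), good [0.75, 0.90], excellent (> 0.9).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ICCRecord",
    "icc_oneway",
    "resampled_icc",
    "classify_icc",
    "build_databank",
    "sample_size_curve",
    "top_variance_features",
    "RobustnessAnalyzer",
]

CLASS_THRESHOLDS = (0.5, 0.75, 0.9)


@dataclass
class ICCRecord:
    """Per-feature robustness summary stored in the databank."""

    feature_name: str
    image_type: str
    family: str
    mean_icc: float
    ci_low: float
    ci_high: float
    class_label: str
    n_patients_per_resample: int
    n_resamples: int


def icc_oneway(values: np.ndarray, formula_variant: str = "shrout_fleiss") -> float:
    """One-way random-effects, absolute-agreement, single-measurement ICC.

    Parameters
    ----------
    values : (n, k) array
        Rows are patients, columns repeated measurements.
    formula_variant : {"shrout_fleiss", "paper_literal"}
        Denominator ``MSn + (k-1) MSW`` (standard) or ``MSn + (k+1) MSW``.

    Returns NaN when both mean squares vanish (a constant matrix carries no
    repeatability information).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) measurement matrix")
    if not np.isfinite(x).all():
        raise ValueError("measurement matrix contains non-finite values")
    n, k = x.shape
    row_means = x.mean(axis=1)
    grand = x.mean()
    ms_between = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_within = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if ms_between == 0.0 and ms_within == 0.0:
        return math.nan
    if formula_variant == "shrout_fleiss":
        denom = ms_between + (k - 1) * ms_within
    elif formula_variant == "paper_literal":
        denom = ms_between + (k + 1) * ms_within
    else:
        raise ValueError(f"unknown formula_variant: {formula_variant!r}")
    return float((ms_between - ms_within) / denom)


def resampled_icc(
    values: np.ndarray,
    n_patients: int | None = None,
    n_rounds: int = 10,
    seed: int = 0,
    formula_variant: str = "shrout_fleiss",
) -> tuple[float, float, float]:
    """Mean ICC and percentile 95% CI over patient-subsampling rounds.

    Each round draws ``n_patients`` rows without replacement and computes the
    ICC; returns (mean, 2.5th, 97.5th percentile).
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.shape[0]
    n_patients = n if n_patients is None else int(n_patients)
    if n_patients > n:
        raise ValueError(f"n_patients={n_patients} exceeds available patients ({n})")
    if n_rounds < 2:
        raise ValueError("n_rounds must be >= 2")
    rng = np.random.default_rng(seed)
    iccs = np.empty(n_rounds)
    for r in range(n_rounds):
        rows = (
            rng.choice(n, size=n_patients, replace=False)
            if n_patients < n
            else np.arange(n)
        )
        iccs[r] = icc_oneway(x[rows], formula_variant)
    if np.isnan(iccs).any():
        return math.nan, math.nan, math.nan
    lo, hi = np.percentile(iccs, [2.5, 97.5])
    return float(iccs.mean()), float(lo), float(hi)


def classify_icc(icc: float) -> str:
    """Repeatability class of an ICC value (NaN -> "degenerate")."""
    if icc is None or math.isnan(icc):
        return "degenerate"
    if icc < CLASS_THRESHOLDS[0]:
        return "poor"
    if icc < CLASS_THRESHOLDS[1]:
        return "moderate"
    if icc <= CLASS_THRESHOLDS[2]:
        return "good"
    return "excellent"


def _feature_meta(name: str) -> tuple[str, str]:
    """(image_type, family) parsed from the feature naming convention."""
    parts = name.split("_")
    if len(parts) >= 2 and parts[1] == "shape":
        return "original", "shape"
    return parts[0], parts[1] if len(parts) > 1 else "unknown"


def _measurement_matrices(feature_table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Pivot a long (patient, measurement) x feature table into per-feature
    n x k matrices, with the unperturbed measurement in column 0."""
    if not isinstance(feature_table.index, pd.MultiIndex):
        raise ValueError(
            "feature table must have a (patient, measurement) MultiIndex"
        )
    patients = feature_table.index.get_level_values(0).unique()
    measurements = feature_table.index.get_level_values(1).unique().tolist()
    if len(feature_table) != len(patients) * len(measurements):
        counts = feature_table.groupby(level=0).size()
        gaps = counts[counts != len(measurements)].index.tolist()
        raise ValueError(f"patients with missing realizations: {gaps}")
    wide = feature_table.unstack(level=1)  # columns: (feature, measurement)
    if "unperturbed" in measurements:
        measurements = ["unperturbed"] + [
            m for m in measurements if m != "unperturbed"
        ]
    return {
        feat: wide[feat][measurements].to_numpy() for feat in feature_table.columns
    }


def build_databank(
    feature_table: pd.DataFrame,
    n_patients_per_resample: int | None = None,
    n_resamples: int = 10,
    seed: int = 0,
    formula_variant: str = "shrout_fleiss",
) -> pd.DataFrame:
    """Assemble the robustness databank: one ICC record per feature.

    ``feature_table`` is long-format: MultiIndex (patient, measurement) rows —
    measurement "unperturbed" plus one id per realization — and one column per
    feature. Features whose matrix contains non-finite values are retained
    with class "degenerate" and a warning rather than dropped silently.
    """
    records = []
    for feat, matrix in _measurement_matrices(feature_table).items():
        img_type, family = _feature_meta(feat)
        if not np.isfinite(matrix).all():
            warnings.warn(f"feature {feat!r} has non-finite measurements; "
                          "recorded as degenerate", stacklevel=2)
            mean = lo = hi = math.nan
        else:
            mean, lo, hi = resampled_icc(
                matrix, n_patients_per_resample, n_resamples, seed, formula_variant
            )
        records.append(
            ICCRecord(
                feature_name=feat,
                image_type=img_type,
                family=family,
                mean_icc=mean,
                ci_low=lo,
                ci_high=hi,
                class_label=classify_icc(mean),
                n_patients_per_resample=(
                    n_patients_per_resample
                    or len(feature_table.index.get_level_values(0).unique())
                ),
                n_resamples=n_resamples,
            )
        )
    df = pd.DataFrame([asdict(r) for r in records]).set_index("feature_name")
    if df.index.has_duplicates:
        raise ValueError("duplicate feature names in databank")
    return df


def databank_class_summary(databank: pd.DataFrame) -> pd.DataFrame:
    """Counts of repeatability classes per feature family and per image type."""
    by_family = databank.groupby("family")["class_label"].value_counts().unstack(fill_value=0)
    by_type = databank.groupby("image_type")["class_label"].value_counts().unstack(fill_value=0)
    by_family["level"] = "family"
    by_type["level"] = "image_type"
    return pd.concat([by_family, by_type])


def default_sample_sizes(n_max: int) -> list[int]:
    """10, 20, ..., 100, then 200, 300, ... up to the cohort size."""
    sizes = [n for n in range(10, min(n_max, 100) + 1, 10)]
    sizes += [n for n in range(200, n_max + 1, 100)]
    return sizes


def sample_size_curve(
    feature_table: pd.DataFrame,
    sizes: list[int] | None = None,
    n_rounds: int = 10,
    seed: int = 0,
    formula_variant: str = "shrout_fleiss",
) -> pd.DataFrame:
    """ICC as a function of cohort size: long table (feature, n, round, icc).

    For each size, ``n_rounds`` random patient subsets are drawn (without
    replacement within a round) and the ICC recomputed per feature.
    """
    matrices = _measurement_matrices(feature_table)
    n_avail = next(iter(matrices.values())).shape[0]
    sizes = sizes or default_sample_sizes(n_avail)
    if max(sizes) > n_avail:
        raise ValueError(f"max size {max(sizes)} exceeds cohort size {n_avail}")
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        for rnd in range(n_rounds):
            sel = rng.choice(n_avail, size=n, replace=False)
            for feat, m in matrices.items():
                rows.append((feat, n, rnd, icc_oneway(m[sel], formula_variant)))
    return pd.DataFrame(rows, columns=["feature", "n", "round", "icc"])


def top_variance_features(curve_table: pd.DataFrame, top_n: int = 6) -> list[str]:
    """Features whose mean ICC varies most across sample sizes.

    Ranks by the variance of the per-size mean ICC; ties broken
    lexicographically by feature name.
    """
    if curve_table.empty:
        raise ValueError("empty sample-size curve table")
    mean_per_size = curve_table.groupby(["feature", "n"])["icc"].mean()
    variances = mean_per_size.groupby("feature").var(ddof=0)
    if top_n > len(variances):
        raise ValueError(
            f"top_n={top_n} exceeds number of features ({len(variances)})"
        )
    order = sorted(variances.index, key=lambda f: (-variances[f], f))
    return order[:top_n]


class RobustnessAnalyzer(BaseEstimator):
    """Estimator wrapper around the databank computation.

    ``fit`` takes the long (patient, measurement) x feature table and exposes
    ``databank_`` (records DataFrame), ``class_summary_`` and the raw
    ``measurement_matrices_``.
    """

    def __init__(
        self,
        formula_variant: str = "shrout_fleiss",
        n_patients_per_resample: int | None = None,
        n_resamples: int = 10,
        seed: int = 0,
    ):
        self.formula_variant = formula_variant
        self.n_patients_per_resample = n_patients_per_resample
        self.n_resamples = n_resamples
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        self.databank_ = build_databank(
            X,
            n_patients_per_resample=self.n_patients_per_resample,
            n_resamples=self.n_resamples,
            seed=self.seed,
            formula_variant=self.formula_variant,
        )
        self.class_summary_ = databank_class_summary(self.databank_)
        return self
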