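"""Risk stratification and model-comparison analyses.

Quartile cutpoints are computed once on tuning-set scores (linear
interpolation quantiles) and frozen before being applied to test subjects;
proportional-hazards fits use Efron tie handling via lifelines. Cox model
comparison fits baseline covariates alone, the AI score alone, and both,
reporting concordance for each and a nested likelihood-ratio test for the
added value of the score. Associations between predictions and echo
measurements are adjusted for sex, age and age squared by linear regression
on standardized variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .metrics import km_curve

logger = logging.getLogger(__name__)

#: Baseline Cox covariate sets used for comparison with the AI score.
BASELINE_COVARIATES = {
    "mr": ["age", "sex", "la_volume", "la_dimension", "lvedd"],
    "ar": ["age", "sex", "aortic_sinus_diameter", "ascending_aorta_diameter", "lvedd"],
    "tr": ["age", "sex", "rv_diameter", "la_volume"],
}

QUARTILE_NAMES = ("low", "intermediate-low", "intermediate-high", "high")


def _encode_sex(series: pd.Series) -> pd.Series:
    if series.dtype == object:
        return (series == "male").astype(float)
    return series.astype(float)


@dataclass
class QuartileStratification:
    cutpoints: np.ndarray
    groups: pd.Series                      # per test subject, category name
    km_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    hazard_ratios: pd.DataFrame            # per quartile vs lowest: HR + CI + p
    model: CoxPHFitter = field(repr=False, default=None)

    @property
    def top_vs_bottom_hr(self) -> float:
        return float(self.hazard_ratios.loc["high", "hr"])


def quartile_stratify(tune_scores, test_records: pd.DataFrame) -> QuartileStratification:
    """Stratify test subjects into risk quartiles frozen on tuning scores.

    ``test_records`` needs columns ``risk``, ``time``, ``event``, ``age``,
    ``sex``. Returns per-group Kaplan-Meier curves and age/sex-adjusted
    hazard ratios of each quartile against the lowest.
    """
    tune_scores = np.asarray(tune_scores, dtype=float)
    cut = np.quantile(tune_scores, [0.25, 0.5, 0.75])  # linear interpolation
    if len(np.unique(cut)) < 3:
        warnings.warn("degenerate quartile cutpoints; groups collapse")
    risk = test_records["risk"].to_numpy(dtype=float)
    idx = np.searchsorted(cut, risk, side="left")
    groups = pd.Series(pd.Categorical.from_codes(
        idx, categories=list(QUARTILE_NAMES)), index=test_records.index)

    curves = {}
    for name in QUARTILE_NAMES:
        sel = groups == name
        if sel.any():
            curves[name] = km_curve(test_records.loc[sel, "time"],
                                    test_records.loc[sel, "event"])

    df = pd.DataFrame({
        "time": test_records["time"].to_numpy(dtype=float),
        "event": test_records["event"].to_numpy().astype(int),
        "age": test_records["age"].to_numpy(dtype=float),
        "sex": _encode_sex(test_records["sex"]),
    })
    for name in QUARTILE_NAMES[1:]:
        df[f"q_{name}"] = (groups == name).to_numpy().astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    rows = {}
    for name in QUARTILE_NAMES[1:]:
        key = f"q_{name}"
        rows[name] = {
            "hr": float(np.exp(cph.params_[key])),
            "ci_low": float(np.exp(cph.confidence_intervals_.loc[key].iloc[0])),
            "ci_high": float(np.exp(cph.confidence_intervals_.loc[key].iloc[1])),
            "p": float(cph.summary.loc[key, "p"]),
        }
    hr = pd.DataFrame(rows).T
    return QuartileStratification(cutpoints=cut, groups=groups,
                                  km_curves=curves, hazard_ratios=hr, model=cph)


# --------------------------------------------------------------------------
# Cox model comparison


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df[["time", "event"] + covariates], duration_col="time",
            event_col="event")
    return cph


def cox_model_comparison(records: pd.DataFrame, baseline_covariates: list[str],
                         ai_col: str = "ai_score") -> dict:
    """Compare baseline-covariate, AI-alone and combined Cox models.

    Complete-case analysis over ``baseline_covariates + [ai_col]``. Returns
    concordance indices for the three models and the nested likelihood-ratio
    test (1 df) of baseline + AI against baseline. Convergence failures
    propagate to the caller.
    """
    cols = ["time", "event"] + list(baseline_covariates) + [ai_col]
    df = records[cols].copy()
    if "sex" in df.columns:
        df["sex"] = _encode_sex(df["sex"])
    df = df.dropna()
    if df["event"].sum() == 0:
        raise ValueError("no events in complete-case records")
    base = _fit_cox(df, list(baseline_covariates))
    ai = _fit_cox(df, [ai_col])
    both = _fit_cox(df, list(baseline_covariates) + [ai_col])
    lrt_chi2 = 2.0 * (both.log_likelihood_ - base.log_likelihood_)
    return {
        "n": int(len(df)),
        "c_baseline": float(base.concordance_index_),
        "c_ai": float(ai.concordance_index_),
        "c_combined": float(both.concordance_index_),
        "lrt_chi2": float(lrt_chi2),
        "lrt_p": float(stats.chi2.sf(max(lrt_chi2, 0.0), df=1)),
        "models": {"baseline": base, "ai": ai, "combined": both},
    }


def fine_gray_competing_risk(*args, **kwargs):  # pragma: no cover - reserved
    """Competing-risk sensitivity analysis (reserved; not computed here)."""
    raise NotImplementedError(
        "Fine-Gray competing-risk analysis is not computed by this package")


def partial_likelihood_ratio_test(*args, **kwargs):  # pragma: no cover - reserved
    """Non-nested Cox comparison (reserved; not computed here)."""
    raise NotImplementedError(
        "the partial likelihood ratio test for non-nested Cox models is not "
        "computed by this package")


# --------------------------------------------------------------------------
# imaging associations


def imaging_association(predictions, measurements: pd.DataFrame, age, sex) -> pd.DataFrame:
    """Adjusted association of predictions with each echo measurement.

    Per measurement: complete cases, standardize both the measurement and
    the prediction, then OLS of the measurement on the prediction adjusted
    for sex, age and age squared. Returns the standardized coefficient with
    its 95% CI and p-value; constant measurements are skipped with a log
    entry.
    """
    pred = np.asarray(predictions, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_num = _encode_sex(pd.Series(sex)).to_numpy()
    rows = []
    for col in measurements.columns:
        m = measurements[col].to_numpy(dtype=float)
        ok = np.isfinite(m) & np.isfinite(pred)
        if ok.sum() < 10 or np.nanstd(m[ok]) == 0:
            logger.info("imaging_association: skipping %s (constant or too few)", col)
            continue
        mz = (m[ok] - m[ok].mean()) / m[ok].std()
        pz = (pred[ok] - pred[ok].mean()) / pred[ok].std()
        design = sm.add_constant(np.column_stack([
            pz, age[ok], age[ok] ** 2, sex_num[ok]]))
        fit = sm.OLS(mz, design).fit()
        ci = fit.conf_int()[1]
        rows.append({"measurement": col, "coef": float(fit.params[1]),
                     "ci_low": float(ci[0]), "ci_high": float(ci[1]),
                     "p": float(fit.pvalues[1]), "n": int(ok.sum())})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# serial trajectories


def serial_trajectory(records: pd.DataFrame, bin_days: int = 90) -> pd.DataFrame:
    """Mean model score against time to diagnosis, in fixed-width day bins.

    ``records`` needs ``score``, ``ecg_date`` and ``event_date`` (the first
    significant-disease echo). Time is ECG date minus event date (negative
    before diagnosis); each bin reports the mean score with a normal 95% CI.
    """
    days = (pd.to_datetime(records["ecg_date"])
            - pd.to_datetime(records["event_date"])).dt.days.to_numpy()
    score = records["score"].to_numpy(dtype=float)
    bins = np.floor(days / bin_days).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        vals = score[sel]
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"bin_start_days": int(b * bin_days), "n": int(sel.sum()),
                     "mean_score": mean,
                     "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se})
    return pd.DataFrame(rows).sort_values("bin_start_days").reset_index(drop=True)
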