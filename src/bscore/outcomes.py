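"""Clinical outcomes and logistic risk modelling.

Outcomes are threshold exceedances of symptom instruments — the 7-day pain
numeric rating scale (NRS, 0-10), WOMAC physical function (0-68) and WOMAC
pain (0-20) — either at baseline ("current") or as the median of all
post-baseline timepoints ("future"), plus adjudicated total knee
replacement (TKR).  Risk is modelled by plain logistic regression against
a continuous B-score, a categorical Kellgren-Lawrence grade (KLG, entered
as indicators with grade 0 as reference), or both; TKR uses the same model
(deliberately not a hazard model).  Within-KLG B-score quartiles give odds
ratios against the lowest quartile, and nested-model AUC comparison
quantifies what the continuous score adds over the grade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score

__all__ = [
    "ClinicalRecord",
    "OutcomeSpec",
    "LogisticFit",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_COVARIATES",
    "current_outcome",
    "future_outcome",
    "outcome_vector",
    "select_function_knee",
    "fit_logistic",
    "klg_design",
    "risk_curve",
    "quartile_or_table",
    "auc",
    "added_value",
    "adjusted_fit",
    "interval_width_ratio",
    "p_stars",
]

SCALE_RANGES = {"nrs_pain": (0, 10), "womac_function": (0, 68), "womac_pain": (0, 20)}

# moderate / severe exceedance thresholds per instrument; the severe
# function default follows the methods definition (>= 35) and is
# overridable for sensitivity analysis (e.g. 32/34/36, or 7/8/9 for pain).
DEFAULT_THRESHOLDS = {
    "nrs_pain": {"moderate": 4, "severe": 8},
    "womac_function": {"moderate": 20, "severe": 35},
    "womac_pain": {"moderate": 4, "severe": 8},
}

DEFAULT_COVARIATES = ("age", "sex", "ethnicity", "bmi", "alignment",
                      "prior_surgery", "nsaid", "smoking")


@dataclass
class ClinicalRecord:
    """Per-knee clinical data: KLG, outcome score series, TKR and covariates.

    Score series are indexed by timepoint with index 0 = baseline; ``None``
    marks a missing assessment.
    """

    knee_id: str
    person_id: str
    sex: str = "female"
    side: str = "right"
    klg: int = 0
    tkr: bool = False
    nrs_pain: list = field(default_factory=list)
    womac_function: list = field(default_factory=list)
    womac_pain: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.klg not in range(5):
            raise ValueError(f"KLG must be 0-4, got {self.klg} for knee {self.knee_id!r}")
        for scale, (lo, hi) in SCALE_RANGES.items():
            for t, v in enumerate(getattr(self, scale)):
                if v is not None and not lo <= v <= hi:
                    raise ValueError(
                        f"{scale} value {v} at timepoint {t} outside [{lo}, {hi}] "
                        f"for knee {self.knee_id!r}")

    def series(self, scale: str) -> list:
        if scale == "tkr":
            raise ValueError("tkr is a flag, not a score series")
        return getattr(self, scale)


@dataclass(frozen=True)
class OutcomeSpec:
    """Which outcome to analyse: instrument, severity threshold and timing."""

    scale: str = "nrs_pain"
    severity: str = "moderate"
    timing: str = "current"
    threshold: float | None = None  # None -> instrument default for severity

    def __post_init__(self) -> None:
        if self.scale not in (*SCALE_RANGES, "tkr"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale != "tkr":
            if self.severity not in ("moderate", "severe"):
                raise ValueError(f"unknown severity {self.severity!r}")
            if self.timing not in ("current", "future"):
                raise ValueError(f"unknown timing {self.timing!r}")

    @property
    def resolved_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return DEFAULT_THRESHOLDS[self.scale][self.severity]


def current_outcome(record: ClinicalRecord, spec: OutcomeSpec) -> bool:
    """Baseline exceedance: score at timepoint 0 at or above the threshold."""
    if spec.scale == "tkr":
        return bool(record.tkr)
    series = record.series(spec.scale)
    if not series or series[0] is None:
        raise ValueError(f"missing baseline {spec.scale} for knee {record.knee_id!r}")
    return series[0] >= spec.resolved_threshold


def future_outcome(record: ClinicalRecord, spec: OutcomeSpec) -> bool:
    """Future exceedance: median of all post-baseline scores vs threshold.

    The median of an even number of follow-ups is the mean of the middle two.
    """
    if spec.scale == "tkr":
        return bool(record.tkr)
    follow = [v for v in record.series(spec.scale)[1:] if v is not None]
    if not follow:
        raise ValueError(f"no follow-up {spec.scale} scores for knee {record.knee_id!r}")
    return float(np.median(follow)) >= spec.resolved_threshold


def outcome_vector(records: Sequence[ClinicalRecord], spec: OutcomeSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the outcome on every record that has the needed data.

    Returns ``(index, y)``: the positions of usable records and their
    boolean outcomes.  Records lacking the required scores are skipped
    (with a logged count) rather than raising.
    """
    evaluate = current_outcome if spec.timing == "current" or spec.scale == "tkr" \
        else future_outcome
    idx, y = [], []
    for i, rec in enumerate(records):
        try:
            y.append(evaluate(rec, spec))
        except ValueError:
            continue
        idx.append(i)
    n_skipped = len(records) - len(idx)
    if n_skipped:
        warnings.warn(f"{n_skipped} records skipped for missing {spec.scale} data",
                      stacklevel=2)
    return np.array(idx, dtype=int), np.array(y, dtype=bool)


def select_function_knee(records: Sequence[ClinicalRecord], bscores: dict) -> str:
    """Pick the analysis knee for a person: highest B-score wins.

    Ties break to the right knee, then to the lexicographically smallest
    knee id.  ``bscores`` maps knee_id -> B-score; unscored knees are
    ignored.
    """
    scored = [r for r in records if r.knee_id in bscores]
    if not scored:
        raise ValueError("no knee with a B-score for this person")
    best = min(scored, key=lambda r: (-bscores[r.knee_id], r.side != "right",
                                      r.knee_id))
    return best.knee_id


@dataclass
class LogisticFit:
    """A fitted logistic regression with its Wald machinery."""

    params: np.ndarray          # coefficient vector, constant first
    names: list                 # column names, ["const", ...]
    cov: np.ndarray             # coefficient covariance matrix
    n: int
    llf: float
    converged: bool
    fitted_probabilities: np.ndarray

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def wald_p(self, name: str) -> float:
        from scipy import stats
        z = self.coef(name) / self.se(name)
        return float(2 * stats.norm.sf(abs(z)))

    def odds_ratio(self, name: str, z: float = 1.96) -> tuple[float, float, float]:
        """(OR, ci_lo, ci_hi) for one coefficient."""
        b, se = self.coef(name), self.se(name)
        with np.errstate(over="ignore"):
            return (float(np.exp(b)), float(np.exp(b - z * se)),
                    float(np.exp(b + z * se)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        design = np.column_stack([np.ones(len(X)), X])
        return expit(design @ self.params)


def fit_logistic(y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None,
                 min_n: int = 10) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    ``X`` holds the predictor columns (no constant; one is added).  Raises
    on a single-class outcome, rank-deficient (collinear) design, or
    detected complete separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and y.size > 1:
        X = X.T
    if len(y) != X.shape[0]:
        raise ValueError("y and X lengths differ")
    if len(y) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(y)}")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit undefined")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = ["const", *names]
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear predictors among {names}")

    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
        except (PerfectSeparationError, PerfectSeparationWarning,
                np.linalg.LinAlgError) as exc:
            raise ValueError(f"logistic fit failed (likely complete separation) "
                             f"for predictors {names[1:]}: {exc}") from exc
    if np.linalg.norm(res.params) > 1e3:
        raise ValueError(f"complete separation detected for predictors {names[1:]}")
    return LogisticFit(
        params=np.asarray(res.params), names=list(names),
        cov=np.asarray(res.cov_params()), n=len(y), llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        fitted_probabilities=np.asarray(res.predict()),
    )


def klg_design(klg: np.ndarray) -> tuple[np.ndarray, list]:
    """KLG as 4 indicator columns, grade 0 as the reference."""
    klg = np.asarray(klg, dtype=int)
    cols = [(klg == g).astype(float) for g in (1, 2, 3, 4)]
    return np.column_stack(cols), ["klg1", "klg2", "klg3", "klg4"]


def risk_curve(fit: LogisticFit, grid: np.ndarray, z: float = 1.96,
               lp_clamp: float = 50.0) -> pd.DataFrame:
    """Predicted outcome risk (%) with Wald CI over predictor values.

    ``grid`` gives predictor rows matching the fit's non-constant columns
    (a 1D grid is treated as a single continuous predictor).  The CI is
    computed on the linear-predictor scale and inverse-logit transformed,
    so it always lies within [0, 100] and brackets the point estimate.
    """
    if not fit.converged:
        raise ValueError("risk_curve requires a converged fit")
    grid = np.asarray(grid, dtype=float)
    flat = grid.ndim == 1
    X = grid.reshape(-1, 1) if flat else grid
    design = np.column_stack([np.ones(len(X)), X])
    lp = design @ fit.params
    if np.any(np.abs(lp) > lp_clamp):
        warnings.warn(f"linear predictor clamped to +-{lp_clamp}", stacklevel=2)
        lp = np.clip(lp, -lp_clamp, lp_clamp)
    se = np.sqrt(np.einsum("ij,jk,ik->i", design, fit.cov, design))
    out = pd.DataFrame({
        "risk": 100.0 * expit(lp),
        "ci_lo": 100.0 * expit(lp - z * se),
        "ci_hi": 100.0 * expit(lp + z * se),
    })
    if flat:
        out.insert(0, "value", grid)
    return out


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) concordance of scores against outcomes."""
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise ValueError("AUC undefined for a single outcome class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def assign_quartiles(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quartile membership (0-3) by sample quantiles, linear interpolation.

    Values equal to a boundary go to the lower quartile.  Returns
    ``(quartile_index, bounds)``.
    """
    values = np.asarray(values, dtype=float)
    bounds = np.quantile(values, [0.25, 0.5, 0.75])
    return np.searchsorted(bounds, values, side="left"), bounds


def quartile_or_table(records: Sequence[ClinicalRecord], bscores: dict,
                      spec: OutcomeSpec, min_stratum: int = 8) -> pd.DataFrame:
    """Within-KLG odds ratios for B-score quartiles 2-4 versus quartile 1.

    Each KLG stratum is split into B-score quartiles; a logistic fit on
    quartile indicators gives Wald ORs, CIs and p-values against the lowest
    quartile.  Strata that are too small or single-class are skipped with a
    warning rather than failing the whole table.
    """
    rows = []
    for grade in range(5):
        stratum = [r for r in records if r.klg == grade and r.knee_id in bscores]
        if len(stratum) < min_stratum:
            warnings.warn(f"KLG {grade}: only {len(stratum)} scored knees, skipped",
                          stacklevel=2)
            continue
        idx, y = outcome_vector(stratum, spec)
        stratum = [stratum[i] for i in idx]
        if len(stratum) < min_stratum or y.min() == y.max():
            warnings.warn(f"KLG {grade}: insufficient outcome variation, skipped",
                          stacklevel=2)
            continue
        b = np.array([bscores[r.knee_id] for r in stratum])
        q, _bounds = assign_quartiles(b)
        X = np.column_stack([(q == j).astype(float) for j in (1, 2, 3)])
        names = ["q2", "q3", "q4"]
        try:
            fit = fit_logistic(y, X, names=names, min_n=min_stratum)
        except ValueError as exc:
            warnings.warn(f"KLG {grade}: {exc}; skipped", stacklevel=2)
            continue
        for quartile, name in zip((2, 3, 4), names):
            or_, lo, hi = fit.odds_ratio(name)
            p = fit.wald_p(name)
            rows.append({"klg": grade, "quartile": quartile, "or": or_,
                         "ci_lo": lo, "ci_hi": hi, "p": p,
                         "stars": p_stars(p), "n_stratum": len(stratum)})
    return pd.DataFrame(rows, columns=["klg", "quartile", "or", "ci_lo", "ci_hi",
                                       "p", "stars", "n_stratum"])


def added_value(records: Sequence[ClinicalRecord], bscores: dict,
                spec: OutcomeSpec) -> dict:
    """Does the continuous B-score add discrimination over categorical KLG?

    Fits outcome ~ KLG and outcome ~ KLG + B-score; reports both AUCs and
    the Wald p-value for the B-score coefficient in the combined model.
    """
    usable = [r for r in records if r.knee_id in bscores]
    idx, y = outcome_vector(usable, spec)
    usable = [usable[i] for i in idx]
    klg = np.array([r.klg for r in usable])
    b = np.array([bscores[r.knee_id] for r in usable])
    X_klg, names = klg_design(klg)
    fit_klg = fit_logistic(y, X_klg, names=names)
    fit_both = fit_logistic(y, np.column_stack([X_klg, b]), names=[*names, "bscore"])
    return {
        "auc_klg": auc(fit_klg.fitted_probabilities, y),
        "auc_klg_plus_b": auc(fit_both.fitted_probabilities, y),
        "p_bscore": fit_both.wald_p("bscore"),
        "fit_klg": fit_klg,
        "fit_combined": fit_both,
        "n": len(y),
    }


def _covariate_design(records: Sequence[ClinicalRecord], covariates: Sequence[str]
                      ) -> tuple[np.ndarray, list, np.ndarray]:
    """Dummy-coded covariate matrix with complete-case row mask.

    Categorical covariates take their most frequent level as the reference;
    zero-variance columns are dropped with a warning.
    """
    frame = {}
    for name in covariates:
        if name == "sex":
            frame[name] = [r.sex for r in records]
        else:
            frame[name] = [r.covariates.get(name) for r in records]
    df = pd.DataFrame(frame)
    mask = df.notna().all(axis=1).to_numpy()
    n_excluded = int((~mask).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} records excluded for missing covariates",
                      stacklevel=3)
    df = df.loc[mask]
    cols, names = [], []
    for name in covariates:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col) and col.dtype != bool:
            values = col.to_numpy(dtype=float)
            if np.ptp(values) == 0:
                warnings.warn(f"covariate {name!r} has zero variance; dropped",
                              stacklevel=3)
                continue
            cols.append(values)
            names.append(name)
        else:
            reference = col.value_counts().idxmax()
            for level in sorted(set(col) - {reference}, key=str):
                indicator = (col == level).to_numpy(dtype=float)
                if np.ptp(indicator) == 0:
                    continue
                cols.append(indicator)
                names.append(f"{name}[{level}]")
            if col.nunique() == 1:
                warnings.warn(f"covariate {name!r} has zero variance; dropped",
                              stacklevel=3)
    X = np.column_stack(cols) if cols else np.empty((mask.sum(), 0))
    return X, names, mask


def adjusted_fit(records: Sequence[ClinicalRecord], bscores: dict, spec: OutcomeSpec,
                 covariates: Sequence[str] = DEFAULT_COVARIATES) -> dict:
    """Confounder-adjusted logistic fit of outcome on B-score.

    Fits outcome ~ B-score + covariates on complete cases and reports the
    B-score odds ratio before and after adjustment.
    """
    usable = [r for r in records if r.knee_id in bscores]
    idx, y_all = outcome_vector(usable, spec)
    usable = [usable[i] for i in idx]
    b = np.array([bscores[r.knee_id] for r in usable])
    X_cov, cov_names, mask = _covariate_design(usable, covariates)
    fit_unadj = fit_logistic(y_all, b.reshape(-1, 1), names=["bscore"])
    fit_adj = fit_logistic(y_all[mask], np.column_stack([b[mask], X_cov]),
                           names=["bscore", *cov_names])
    return {
        "fit": fit_adj,
        "fit_unadjusted": fit_unadj,
        "or_unadjusted": fit_unadj.odds_ratio("bscore"),
        "or_adjusted": fit_adj.odds_ratio("bscore"),
        "n_complete": int(mask.sum()),
        "n_excluded": int((~mask).sum()),
    }


def interval_width_ratio(wide: tuple[float, float], narrow: tuple[float, float]) -> float:
    """Ratio of two confidence-interval widths (e.g. misclassification-widened
    risk CI over the single-grade CI)."""
    w = wide[1] - wide[0]
    n = narrow[1] - narrow[0]
    if w < 0 or n <= 0:
        raise ValueError("intervals must be ordered and the narrow one non-empty")
    return w / n


def p_stars(p: float) -> str:
    """Significance stars at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
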