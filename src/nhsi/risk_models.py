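"""Propensity logistic models, discrimination, and decile stratification.

Three fixed model specifications predict pressure-injury development:
model 1 uses the Worst-Braden total alone, model 2 the four severity
dimension scores, model 3 all five predictors.  Fits are maximum-likelihood
logistic regressions (Newton iterations, Wald inference); fitted
probabilities are the propensity scores used for decile stratification, and
discrimination is the C statistic (concordance probability, ties counted
one half).  A nested pair of fits can be compared with a likelihood-ratio
chi-square; non-nested pairs are refused and reported descriptively as a
C-statistic difference instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

WORST_BRADEN = "worst_braden"
DIMENSION_COLS = ("laboratory", "weights_vitals_pain", "locomotion", "underweight")

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    predictors: tuple[str, ...]


MODEL_SPECS = (
    ModelSpec("model1_braden", (WORST_BRADEN,)),
    ModelSpec("model2_nhsi", DIMENSION_COLS),
    ModelSpec("model3_combined", (WORST_BRADEN,) + DIMENSION_COLS),
)


class PropensityModel(BaseEstimator):
    """Sklearn-style logistic propensity model backed by statsmodels.

    Parameters
    ----------
    predictors : sequence of str, optional
        Column subset to use when ``X`` is a DataFrame; all columns if None.
    tol : float
        Convergence tolerance of the Newton maximum-likelihood iterations.

    Fitted attributes (trailing underscore): ``coef_``, ``intercept_``,
    ``se_``, ``pvalues_``, ``odds_ratios_``, ``or_conf_int_`` (95% Wald),
    ``llf_``, ``c_statistic_`` (in-sample), ``propensity_`` (in-sample fitted
    probabilities), ``n_``, ``feature_names_in_``.
    """

    def __init__(self, predictors: Optional[Sequence[str]] = None, tol: float = 1e-8):
        self.predictors = predictors
        self.tol = tol

    # -- helpers -----------------------------------------------------------
    def _design(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            cols = list(self.predictors) if self.predictors is not None else list(X.columns)
            mat = X[cols].to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat[:, None]
            cols = (
                list(self.predictors)
                if self.predictors is not None
                else [f"x{i}" for i in range(mat.shape[1])]
            )
            if len(cols) != mat.shape[1]:
                raise ModelError(
                    f"{mat.shape[1]} columns but {len(cols)} predictor names"
                )
        return mat, cols

    def fit(self, X, y) -> "PropensityModel":
        mat, cols = self._design(X)
        y = np.asarray(y, dtype=float)
        if mat.shape[0] != y.shape[0]:
            raise ModelError("X and y lengths differ")
        classes = np.unique(y)
        if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
            raise ModelError("outcome must contain both classes coded 0/1")
        for j, c in enumerate(cols):
            if np.ptp(mat[:, j]) == 0:
                raise ModelError(f"predictor {c!r} is constant")
        design = sm.add_constant(mat, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, design).fit(
                    disp=0, method="newton", tol=self.tol, maxiter=200
                )
            except Exception as err:  # separation, singularity, ...
                raise ModelError(f"logistic fit failed: {err}") from err
        if not res.mle_retvals.get("converged", False):
            raise ModelError(
                "logistic fit did not converge "
                f"(iterations={res.mle_retvals.get('iterations')}, "
                f"|params| max={np.abs(res.params).max():.3g})"
            )
        if np.abs(res.params).max() > 50:
            raise ModelError(
                "coefficients diverged — likely complete/quasi separation"
            )
        params = np.asarray(res.params)
        se = np.asarray(res.bse)
        self.feature_names_in_ = cols
        self.intercept_ = float(params[0])
        self.intercept_se_ = float(se[0])
        self.coef_ = params[1:].copy()
        self.se_ = se[1:].copy()
        self.pvalues_ = np.asarray(res.pvalues)[1:].copy()
        self.odds_ratios_ = np.exp(self.coef_)
        self.or_conf_int_ = np.exp(
            np.column_stack(
                [self.coef_ - Z_95 * self.se_, self.coef_ + Z_95 * self.se_]
            )
        )
        self.llf_ = float(res.llf)
        self.n_ = int(y.shape[0])
        self.propensity_ = np.asarray(res.predict(design))
        self.c_statistic_ = c_statistic(y, self.propensity_)
        self.classes_ = np.array([0, 1])
        return self

    def predict_propensity(self, X) -> np.ndarray:
        mat, _ = self._design(X)
        eta = self.intercept_ + mat @ self.coef_
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_propensity(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_propensity(X) >= 0.5).astype(int)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient / OR table shaped like a published model table."""
        return pd.DataFrame(
            {
                "estimate": self.coef_,
                "se": self.se_,
                "p_value": self.pvalues_,
                "odds_ratio": self.odds_ratios_,
                "or_ci_low": self.or_conf_int_[:, 0],
                "or_ci_high": self.or_conf_int_[:, 1],
            },
            index=pd.Index(self.feature_names_in_, name="predictor"),
        )


def fit_logistic(outcome, predictors, names: Optional[Sequence[str]] = None) -> PropensityModel:
    """Fit a logistic propensity model; functional wrapper."""
    return PropensityModel(predictors=names).fit(predictors, outcome)


def c_statistic(outcome, propensity) -> float:
    """Concordance probability (AUC): chance a random case outranks a random
    non-case, ties counted one half.  0.5 is chance, 1.0 perfect."""
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(propensity, dtype=float)
    if len(np.unique(y)) < 2:
        raise ModelError("C statistic needs both outcome classes")
    if np.ptp(p) == 0:
        return 0.5
    return float(roc_auc_score(y, p))


def lr_chi_square(
    fit_full: PropensityModel, fit_reduced: PropensityModel
) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square between nested fits on the same subjects.

    Returns ``(statistic, df, p)`` with statistic ``2*(LL_full - LL_reduced)``
    and df the parameter-count difference.  Refuses non-nested pairs.
    """
    full = set(fit_full.feature_names_in_)
    reduced = set(fit_reduced.feature_names_in_)
    if not reduced <= full:
        raise ModelError(
            "models are not nested: reduced-model predictors "
            f"{sorted(reduced - full)} absent from the full model; a "
            "likelihood-ratio test is undefined — compare C statistics "
            "descriptively instead"
        )
    if fit_full.n_ != fit_reduced.n_:
        raise ModelError("nested comparison requires the same subjects")
    df = len(full) - len(reduced)
    stat = max(0.0, 2.0 * (fit_full.llf_ - fit_reduced.llf_))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def percent_improvement(c_base: float, c_new: float) -> float:
    """Relative C-statistic improvement in percent, to one decimal."""
    if not c_base > 0:
        raise ModelError("base C statistic must be positive")
    return round(100.0 * (c_new - c_base) / c_base, 1)


@dataclass
class PropensityStratification:
    """Decile stratification of sorted propensity scores."""

    decile_table: pd.DataFrame  # columns: decile, n, pri
    boundaries: np.ndarray  # score cut points between deciles (len 9)
    top3_capture_count: int
    top3_capture_percent: float

    @property
    def total_pri(self) -> int:
        return int(self.decile_table["pri"].sum())


def propensity_deciles(outcome, propensity) -> PropensityStratification:
    """Split subjects into 10 equal strata of sorted propensity.

    Remainder subjects (n not divisible by 10) are spread one-per-stratum
    over the *highest* deciles; ties keep their stable sorted order.  Capture
    is the share of all PrIs falling in the three highest deciles.
    """
    y = np.asarray(outcome, dtype=int)
    p = np.asarray(propensity, dtype=float)
    n = len(y)
    if n < 10:
        raise ModelError(f"decile stratification needs n >= 10, got {n}")
    order = np.argsort(p, kind="stable")
    base, rem = divmod(n, 10)
    sizes = np.full(10, base, dtype=int)
    if rem:
        sizes[-rem:] += 1
    stops = np.cumsum(sizes)
    starts = stops - sizes
    rows = []
    bounds = []
    for d in range(10):
        idx = order[starts[d] : stops[d]]
        rows.append({"decile": d + 1, "n": int(sizes[d]), "pri": int(y[idx].sum())})
        if d < 9:
            bounds.append(p[order[stops[d] - 1]])
    table = pd.DataFrame(rows)
    top3 = int(table.loc[table["decile"] >= 8, "pri"].sum())
    total = int(y.sum())
    return PropensityStratification(
        decile_table=table,
        boundaries=np.asarray(bounds),
        top3_capture_count=top3,
        top3_capture_percent=100.0 * top3 / total if total else float("nan"),
    )


def split_train_validation(
    cohort: pd.DataFrame,
    fraction: float = 0.65,
    seed: Optional[int] = None,
    outcome_col: str = "pri",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform random split into training / validation subsets.

    Training size is ``round(fraction * n)``.  The seed is a required,
    logged input — there is no hidden global state.  A warning is raised if
    either side loses an outcome class.
    """
    if seed is None:
        raise ModelError("split_train_validation requires an explicit seed")
    n = len(cohort)
    if n < 20:
        raise ModelError(f"cohort too small to split (n={n})")
    y = cohort[outcome_col].astype(int)
    if y.nunique() < 2:
        raise ModelError("cohort must contain both outcome classes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    train = cohort.iloc[np.sort(perm[:n_train])]
    valid = cohort.iloc[np.sort(perm[n_train:])]
    for name, part in (("training", train), ("validation", valid)):
        if part[outcome_col].astype(int).nunique() < 2:
            warnings.warn(
                f"{name} subset lost an outcome class; refit may fail",
                stacklevel=2,
            )
    return train, valid


@dataclass
class ModelSuiteReport:
    """Everything the three-model validation workflow produces."""

    fits: dict[str, PropensityModel]
    c_statistics: dict[str, float]
    lr_model3_vs_model1: tuple[float, int, float]
    delta_c_model2_vs_model1: float
    delta_c_caveat: str
    pct_improvement_model2: float
    pct_improvement_model3: float
    deciles: dict[str, PropensityStratification]
    split_c_statistics: dict[str, dict[str, float]] = field(default_factory=dict)
    split_sizes: dict[str, tuple[int, int]] = field(default_factory=dict)
    seed: Optional[int] = None

    def coefficient_tables(self) -> dict[str, pd.DataFrame]:
        return {mid: fit.summary_frame() for mid, fit in self.fits.items()}


def run_model_suite(
    cohort: pd.DataFrame,
    outcome_col: str = "pri",
    seed: Optional[int] = None,
    split_fraction: float = 0.65,
) -> ModelSuiteReport:
    """Fit the three propensity models and the full validation workflow.

    ``cohort`` must carry the Worst-Braden and four dimension-score columns
    plus the binary outcome.  Demographic covariates are deliberately not in
    any specification.  Model 2 vs model 1 is non-nested, so it is reported
    as a descriptive C-statistic difference; model 3 vs model 1 is the nested
    likelihood-ratio test.
    """
    y = cohort[outcome_col].astype(int)
    fits: dict[str, PropensityModel] = {}
    deciles: dict[str, PropensityStratification] = {}
    for spec in MODEL_SPECS:
        fit = PropensityModel(predictors=spec.predictors).fit(cohort, y)
        fits[spec.model_id] = fit
        deciles[spec.model_id] = propensity_deciles(y, fit.propensity_)
    c = {mid: fit.c_statistic_ for mid, fit in fits.items()}
    lr = lr_chi_square(fits["model3_combined"], fits["model1_braden"])
    report = ModelSuiteReport(
        fits=fits,
        c_statistics=c,
        lr_model3_vs_model1=lr,
        delta_c_model2_vs_model1=c["model2_nhsi"] - c["model1_braden"],
        delta_c_caveat=(
            "model 2 and model 1 are not nested; a likelihood-ratio test is "
            "undefined, so their contrast is reported only as a descriptive "
            "C-statistic difference"
        ),
        pct_improvement_model2=percent_improvement(
            c["model1_braden"], c["model2_nhsi"]
        ),
        pct_improvement_model3=percent_improvement(
            c["model1_braden"], c["model3_combined"]
        ),
        deciles=deciles,
        seed=seed,
    )
    if seed is not None:
        train, valid = split_train_validation(
            cohort, fraction=split_fraction, seed=seed, outcome_col=outcome_col
        )
        report.split_sizes = {
            "training": (len(train), int(train[outcome_col].sum())),
            "validation": (len(valid), int(valid[outcome_col].sum())),
        }
        for spec in MODEL_SPECS:
            fit_t = PropensityModel(predictors=spec.predictors).fit(
                train, train[outcome_col].astype(int)
            )
            c_train = fit_t.c_statistic_
            c_valid = c_statistic(
                valid[outcome_col].astype(int),
                fit_t.predict_propensity(valid),
            )
            report.split_c_statistics[spec.model_id] = {
                "training": c_train,
                "validation": c_valid,
            }
    return report
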