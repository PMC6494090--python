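"""Logistic modelling of disease status from retinal structure.

The design table has one row per analysis unit — by default one row per
eye carrying its subject's outcome (1 = Parkinson's, 0 = control) — with
named numeric predictors (the nine ETDRS sector means, foveal pit
metrics, and a sex indicator coded 1 = female).  On top of a
maximum-likelihood logistic fit (Newton-Raphson / iteratively reweighted
least squares) the module provides:

* forward variable selection minimising AIC, with optional forced-in
  covariates and a deterministic name-order tie break;
* Wald odds ratios with 95% confidence limits;
* a two-way interaction screen (product terms added one pair at a time);
* ROC curves and the C-statistic, apparent and leave-one-out
  cross-validated.  LOOCV leaves out whole *subjects*, not rows, so a
  subject's two eyes can never appear on both sides of a fold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

#: Absolute standardised-coefficient threshold taken to signal separation.
SEPARATION_BETA = 15.0
MAX_ITER = 100
TOL = 1e-8


class FitError(RuntimeError):
    """The logistic fit is impossible for structural reasons."""


@dataclass
class RocResult:
    """ROC curve points and the C-statistic (area under the curve)."""

    points: np.ndarray  # (n, 2) of (FPR, TPR), sorted
    c_statistic: float
    ci: Optional[tuple[float, float]] = None
    cross_validated: bool = False


class LogisticModel:
    """Binary logistic regression model (statsmodels-style).

    Parameters
    ----------
    endog : array-like of {0, 1}
        Outcome per row (1 = case).
    exog : DataFrame
        Named numeric predictors, without an intercept column (one is
        always added).
    subject_ids : sequence, optional
        Grouping labels used by subject-level cross-validation.
    """

    def __init__(self, endog, exog: pd.DataFrame, subject_ids=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = pd.DataFrame(exog).astype(float).reset_index(drop=True)
        if self.endog.ndim != 1 or len(self.endog) != len(self.exog):
            raise FitError("endog and exog lengths differ")
        if len(self.endog) < 10:
            raise FitError("need at least 10 rows")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise FitError("outcome must be coded 0/1")
        if len(np.unique(self.endog)) < 2:
            raise FitError("both outcome classes must be present")
        if self.exog.isna().any().any():
            raise FitError("predictor columns must be complete")
        self.subject_ids = (
            np.asarray(subject_ids) if subject_ids is not None else np.arange(len(self.endog))
        )
        self.exog_names = ["intercept"] + list(self.exog.columns)
        self._X = np.column_stack([np.ones(len(self.exog)), self.exog.to_numpy()])
        self._check_rank()

    @classmethod
    def from_design(
        cls,
        table: pd.DataFrame,
        predictors: Sequence[str],
        outcome_col: str = "outcome",
        subject_col: str = "subject_id",
    ) -> "LogisticModel":
        """Build the model from a design table with named columns."""
        missing = [c for c in list(predictors) + [outcome_col] if c not in table.columns]
        if missing:
            raise FitError(f"design table lacks columns {missing}")
        sid = table[subject_col] if subject_col in table.columns else None
        return cls(table[outcome_col].to_numpy(), table[list(predictors)], sid)

    def _check_rank(self) -> None:
        X = self._X
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the culprits via the QR diagonal
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = [self.exog_names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
            raise FitError(f"rank-deficient design; collinear columns: {bad}")

    def fit(self) -> "LogisticResults":
        """Maximum-likelihood fit by Newton-Raphson (IRLS).

        Convergence when the largest coefficient update falls below 1e-8,
        capped at 100 iterations.  Quasi-complete separation is flagged
        when any standardised coefficient exceeds 15 in absolute value;
        such fits are returned with ``converged=False``.
        """
        X, y = self._X, self.endog
        n, k = X.shape
        beta = np.zeros(k)
        converged = False
        for _ in range(MAX_ITER):
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
            w = np.clip(p * (1 - p), 1e-10, None)
            grad = X.T @ (y - p)
            H = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if np.max(np.abs(step)) < TOL:
                converged = True
                break
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(p * (1 - p), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
            bse = np.full(k, np.nan)
        llf = float(np.sum(y * np.log(np.clip(p, 1e-300, None))
                           + (1 - y) * np.log(np.clip(1 - p, 1e-300, None))))
        scale = np.concatenate([[1.0], self.exog.std(ddof=0).to_numpy()])
        separation = bool(np.any(np.abs(beta * scale)[1:] > SEPARATION_BETA))
        return LogisticResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            cov=cov,
            llf=llf,
            fittedvalues=p,
            converged=converged and not separation,
            separation=separation,
        )


class LogisticResults:
    """Results of a logistic fit: coefficients, AIC, probabilities, tables."""

    def __init__(self, model, params, bse, cov, llf, fittedvalues, converged, separation):
        self.model = model
        self.params = params
        self.bse = bse
        self.cov = cov
        self.llf = llf
        self.fittedvalues = fittedvalues
        self.converged = converged
        self.separation = separation

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(exog)), exog[list(self.params.index[1:])].to_numpy()]
        )
        return 1.0 / (1.0 + np.exp(-np.clip(X @ self.params.to_numpy(), -500, 500)))

    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def pvalues(self) -> pd.Series:
        z = self.zvalues()
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def odds_ratios(self) -> pd.DataFrame:
        """Wald odds ratios: exp(β) with exp(β ± 1.96·SE) limits and p-values."""
        if not self.converged:
            raise FitError("odds ratios require a converged fit")
        rows = []
        for name in self.params.index:
            if name == "intercept":
                continue
            b, se = self.params[name], self.bse[name]
            rows.append(
                {
                    "predictor": name,
                    "odds_ratio": np.exp(b),
                    "ci_low": np.exp(b - 1.96 * se),
                    "ci_high": np.exp(b + 1.96 * se),
                    "p_value": 2 * stats.norm.sf(abs(b / se)),
                }
            )
        return pd.DataFrame(rows).set_index("predictor")

    def roc(self) -> RocResult:
        """Apparent (in-sample) ROC of the fitted probabilities."""
        return roc_and_c(self.fittedvalues, self.model.endog)

    def summary(self) -> str:
        p = self.pvalues()
        lines = [
            "Logistic regression (PD status)",
            "=" * 54,
            f"n obs          {len(self.model.endog):>8}",
            f"log-likelihood {self.llf:>12.4f}",
            f"AIC            {self.aic:>12.4f}",
            f"converged      {str(self.converged):>8}"
            + ("   [separation detected]" if self.separation else ""),
            "-" * 54,
            f"{'term':<18}{'coef':>10}{'se':>10}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<18}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}{p[name]:>10.4f}"
            )
        return "\n".join(lines)


def fit_logistic(
    table: pd.DataFrame,
    predictors: Sequence[str],
    outcome_col: str = "outcome",
    subject_col: str = "subject_id",
) -> LogisticResults:
    """Fit a logistic model of the outcome on the named predictors."""
    return LogisticModel.from_design(table, predictors, outcome_col, subject_col).fit()


def forward_select(
    table: pd.DataFrame,
    candidates: Sequence[str],
    forced: Sequence[str] = (),
    outcome_col: str = "outcome",
    subject_col: str = "subject_id",
) -> tuple[LogisticResults, pd.DataFrame]:
    """Forward selection minimising AIC.

    Starts from the forced covariates (or intercept only), and at each
    step adds the candidate whose inclusion gives the lowest AIC,
    stopping when no addition lowers the current AIC.  Ties break by
    candidate name order; candidates whose fit fails are skipped with a
    logged note.  Returns the final fit and the per-step trace.
    """
    candidates = sorted(candidates)
    forced = list(forced)
    if not candidates:
        raise FitError("no candidates supplied")
    if set(candidates) & set(forced):
        raise FitError("candidates and forced sets must be disjoint")
    selected = list(forced)
    current = fit_logistic(table, selected, outcome_col, subject_col)
    trace_rows = [
        {"step": 0, "candidate": "+".join(forced) if forced else "(intercept)",
         "aic": current.aic, "selected": True}
    ]
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        best_name, best_fit = None, None
        for name in remaining:
            try:
                trial = fit_logistic(table, selected + [name], outcome_col, subject_col)
            except FitError as exc:
                logger.info("forward_select: skipping %s (%s)", name, exc)
                trace_rows.append(
                    {"step": step, "candidate": name, "aic": np.nan, "selected": False}
                )
                continue
            trace_rows.append(
                {"step": step, "candidate": name, "aic": trial.aic, "selected": False}
            )
            if best_fit is None or trial.aic < best_fit.aic - 1e-12:
                best_name, best_fit = name, trial
        if best_fit is None or best_fit.aic >= current.aic:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current = best_fit
        for row in trace_rows:
            if row["step"] == step and row["candidate"] == best_name:
                row["selected"] = True
    trace = pd.DataFrame(trace_rows)
    return current, trace


def correlation_matrix(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations with a unit diagonal.

    Zero-variance columns are flagged (logged) and their off-diagonal
    entries set to NaN.
    """
    sub = table[list(columns)].astype(float)
    corr = sub.corr()
    np.fill_diagonal(corr.values, 1.0)
    for col in columns:
        if sub[col].std() == 0:
            logger.warning("correlation_matrix: zero-variance column %s", col)
            corr.loc[col, corr.columns != col] = np.nan
            corr.loc[corr.index != col, col] = np.nan
            corr.loc[col, col] = 1.0
    return corr


def wald_odds_ratios(fit: LogisticResults) -> pd.DataFrame:
    """Per-predictor Wald odds ratios (OR, 95% limits, p)."""
    return fit.odds_ratios()


def interaction_screen(
    table: pd.DataFrame,
    base: Sequence[str],
    outcome_col: str = "outcome",
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Wald p-value of each two-way product term added to the base model.

    Each pair of base predictors is screened separately (base + one
    product term); no multiplicity correction is applied, so treat small
    p-values as hypotheses, not discoveries.
    """
    base = list(base)
    rows = []
    for x1, x2 in itertools.combinations(base, 2):
        term = f"{x1}:{x2}"
        aug = table.copy()
        aug[term] = aug[x1] * aug[x2]
        try:
            fit = fit_logistic(aug, base + [term], outcome_col, subject_col)
            p = float(fit.pvalues()[term]) if fit.converged else np.nan
            err = "" if fit.converged else "fit not converged"
        except FitError as exc:
            p, err = np.nan, str(exc)
        rows.append({"pair": term, "p_value": p, "note": err})
    return pd.DataFrame(rows)


def roc_and_c(scores, labels) -> RocResult:
    """ROC curve (threshold sweep) and C-statistic (trapezoidal area).

    The area equals the concordant-pair fraction with ties counted 1/2:
    the probability a random case scores above a random control.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise FitError("both classes must be present in labels")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(points=np.column_stack([fpr, tpr]), c_statistic=float(_sk_auc(fpr, tpr)))


def loocv_roc(
    table: pd.DataFrame,
    predictors: Sequence[str],
    outcome_col: str = "outcome",
    subject_col: str = "subject_id",
    n_boot: int = 2000,
    seed: int = 0,
    reselect_per_fold: bool = False,
    candidates: Sequence[str] = (),
    forced: Sequence[str] = (),
) -> RocResult:
    """Leave-one-subject-out cross-validated ROC and C-statistic.

    Each fold drops *all* rows of one subject, refits the coefficients on
    the remainder, and predicts the held-out rows; the ROC is computed on
    the pooled out-of-fold probabilities.  By default the predictor set
    is fixed across folds (coefficients only are re-estimated); with
    ``reselect_per_fold`` the forward selection itself is re-run inside
    every fold, a stricter protocol.  The optional confidence interval
    for C is a seeded bootstrap over subjects on the pooled predictions.
    """
    if len(table) < 20:
        raise FitError("LOOCV needs at least 20 rows")
    if subject_col not in table.columns:
        raise FitError(f"LOOCV requires a {subject_col} column")
    table = table.reset_index(drop=True)
    preds = np.full(len(table), np.nan)
    subjects = table[subject_col].to_numpy()
    for sid in pd.unique(subjects):
        test = subjects == sid
        train = table[~test]
        if len(np.unique(train[outcome_col])) < 2:
            raise FitError(f"fold for subject {sid!r} has single-class training data")
        if reselect_per_fold:
            fit, _ = forward_select(train, candidates, forced, outcome_col, subject_col)
            fold_predictors = list(fit.params.index[1:])
        else:
            fold_predictors = list(predictors)
            fit = fit_logistic(train, fold_predictors, outcome_col, subject_col)
        preds[test] = fit.predict(table.loc[test, fold_predictors])
    assert not np.isnan(preds).any()
    result = roc_and_c(preds, table[outcome_col])
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        uniq = pd.unique(subjects)
        groups = {sid: np.where(subjects == sid)[0] for sid in uniq}
        cs = []
        y = table[outcome_col].to_numpy()
        for _ in range(n_boot):
            take = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([groups[s] for s in take])
            if len(np.unique(y[idx])) < 2:
                continue
            cs.append(roc_and_c(preds[idx], y[idx]).c_statistic)
        if cs:
            ci = (float(np.percentile(cs, 2.5)), float(np.percentile(cs, 97.5)))
    return RocResult(
        points=result.points,
        c_statistic=result.c_statistic,
        ci=ci,
        cross_validated=True,
    )
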