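"""Normalized-predictor linear models of perceptual restoration.

The modelling interface follows the Model/Results idiom: build a
:class:`RestorationModel` from a measure table (predictors are z-scored, so
each beta is the change in percent-correct per one SD of the ability), call
``fit()`` for a :class:`RestorationResults` carrying coefficients, 95%
confidence intervals, t and p values, R^2 / adjusted R^2 and the model F,
then ``diagnostics()`` for VIF, a studentized Breusch-Pagan test and a
Shapiro-Wilk test of the residuals.

:func:`purposeful_selection` implements the iterative covariate-selection
procedure: starting from a saturated model, non-hypothesis predictors whose
p-values exceed ``p_stay`` are removed one at a time (largest p first); a
removal that shifts any retained coefficient by more than ``delta_beta_max``
(relative) marks the removed predictor as a relevant adjuster and locks it
back in. Pairwise interactions among survivors are then screened one by one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "RestorationModel",
    "RestorationResults",
    "DiagnosticsReport",
    "SelectionResult",
    "purposeful_selection",
]


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant predictor(s): {bad}")
    return (frame - frame.mean()) / sd


@dataclass(frozen=True)
class DiagnosticsReport:
    """Collinearity, homoscedasticity and residual-normality checks."""

    vif: pd.Series
    bp_stat: float
    bp_p: float
    shapiro_stat: float
    shapiro_p: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"diagnostic": f"VIF[{name}]", "statistic": v, "p": np.nan}
            for name, v in self.vif.items()
        ]
        rows.append({"diagnostic": "breusch_pagan", "statistic": self.bp_stat, "p": self.bp_p})
        rows.append({"diagnostic": "shapiro_wilk", "statistic": self.shapiro_stat, "p": self.shapiro_p})
        return pd.DataFrame(rows)


class RestorationModel:
    """OLS of a condition score on z-scored ability predictors."""

    def __init__(self, data: pd.DataFrame, outcome: str, predictors):
        predictors = list(predictors)
        if not predictors:
            raise ValueError("need at least one predictor")
        cols = [outcome] + predictors
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        frame = data[cols].dropna()
        if len(frame) < len(predictors) + 2:
            raise ValueError("too few complete cases for the design")
        self.outcome = outcome
        self.predictor_names = predictors
        self.endog = frame[outcome].astype(float)
        self.exog_z = _zscore(frame[predictors].astype(float))
        X = sm.add_constant(self.exog_z)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("rank-deficient design (collinear predictors)")
        self._X = X

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, predictors) -> "RestorationModel":
        return cls(data, outcome, predictors)

    def fit(self) -> "RestorationResults":
        res = sm.OLS(self.endog, self._X).fit()
        return RestorationResults(self, res)


class RestorationResults:
    """Fitted normalized-predictor model: estimates, uncertainty, diagnostics."""

    def __init__(self, model: RestorationModel, sm_results):
        self.model = model
        self._res = sm_results

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def tvalues(self) -> pd.Series:
        return self._res.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        ci.columns = ["lower", "upper"]
        return ci

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self._res.rsquared_adj)

    @property
    def fvalue(self) -> float:
        return float(self._res.fvalue)

    @property
    def f_pvalue(self) -> float:
        return float(self._res.f_pvalue)

    @property
    def resid(self) -> pd.Series:
        return self._res.resid

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    # -- reporting ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Table-style report: beta, CI, t, p per predictor."""
        ci = self.conf_int()
        return pd.DataFrame({
            "beta": self.params,
            "ci_lower": ci["lower"],
            "ci_upper": ci["upper"],
            "t": self.tvalues,
            "p": self.pvalues,
        })

    def summary(self) -> str:
        lines = [
            f"Outcome: {self.model.outcome}   n = {self.nobs}",
            f"R^2 = {self.rsquared:.3f}   adj R^2 = {self.rsquared_adj:.3f}   "
            f"F = {self.fvalue:.2f} (p = {self.f_pvalue:.4g})",
            "",
            f"{'predictor':<28}{'beta':>9}{'ci95':>20}{'t':>8}{'p':>9}",
        ]
        ci = self.conf_int()
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>9.3f}"
                f"{'[' + format(ci.loc[name, 'lower'], '.2f') + ', ' + format(ci.loc[name, 'upper'], '.2f') + ']':>20}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>9.4f}"
            )
        return "\n".join(lines)

    # -- diagnostics -------------------------------------------------------
    def diagnostics(self) -> DiagnosticsReport:
        """VIF per predictor, studentized Breusch-Pagan, Shapiro-Wilk."""
        Xz = self.model.exog_z
        if Xz.shape[1] < 2:
            vif = pd.Series([1.0] * Xz.shape[1], index=Xz.columns)
        else:
            Xc = sm.add_constant(Xz).to_numpy()
            vif = pd.Series(
                [variance_inflation_factor(Xc, i + 1) for i in range(Xz.shape[1])],
                index=Xz.columns,
            )
        if not np.all(np.isfinite(vif)):
            raise ValueError("infinite VIF: perfectly collinear predictors")
        _, _, f_stat, f_p = het_breuschpagan(self.resid, self.model._X)
        sh = sps.shapiro(self.resid)
        return DiagnosticsReport(vif, float(f_stat), float(f_p), float(sh.statistic), float(sh.pvalue))


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of purposeful selection."""

    predictors: tuple
    interactions: tuple
    audit: tuple  # dicts: one record per step

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.audit))


def _fit(data, outcome, predictors):
    return RestorationModel(data, outcome, predictors).fit()


def purposeful_selection(
    data: pd.DataFrame,
    outcome: str,
    saturated,
    hypothesis_set=(),
    p_stay: float = 0.25,
    delta_beta_max: float = 0.20,
    alpha_interaction: float = 0.05,
    literal_direction: bool = False,
) -> SelectionResult:
    """Iterative covariate selection with a delta-beta reinstatement check.

    ``literal_direction=True`` reproduces the inverted reading under which a
    predictor is removed when its p-value is *below* ``p_stay``; the default
    removes when p exceeds ``p_stay`` (the cited method's direction).
    """
    saturated = list(saturated)
    if not saturated:
        raise ValueError("saturated predictor set is empty")
    hypothesis_set = set(hypothesis_set)
    if not hypothesis_set <= set(saturated):
        raise ValueError("hypothesis_set must be a subset of the saturated set")

    current = list(saturated)
    locked = set(hypothesis_set)
    audit = []
    fit = _fit(data, outcome, current)
    while True:
        pvals = fit.pvalues.drop("const")
        candidates = {
            name: p for name, p in pvals.items()
            if name not in locked and (p < p_stay if literal_direction else p > p_stay)
        }
        if not candidates:
            break
        if literal_direction:
            victim = min(candidates, key=candidates.get)
        else:
            victim = max(candidates, key=candidates.get)
        reduced = [p for p in current if p != victim]
        if not reduced:
            break
        new_fit = _fit(data, outcome, reduced)
        old_beta = fit.params
        deltas = {}
        for name in reduced:
            b0 = old_beta[name]
            if abs(b0) > 1e-8:
                deltas[name] = abs((new_fit.params[name] - b0) / b0)
        max_delta = max(deltas.values(), default=0.0)
        if max_delta > delta_beta_max:
            locked.add(victim)
            audit.append({
                "step": "reinstate", "predictor": victim,
                "p": float(candidates[victim]), "max_delta_beta": float(max_delta),
            })
        else:
            current = reduced
            fit = new_fit
            audit.append({
                "step": "remove", "predictor": victim,
                "p": float(candidates[victim]), "max_delta_beta": float(max_delta),
            })

    # interaction screen: pairwise products of survivors, one at a time
    interactions = []
    work = data.copy()
    for i in range(len(current)):
        for j in range(i + 1, len(current)):
            a, b = current[i], current[j]
            name = f"{a}:{b}"
            za = _zscore(work[[a]].astype(float))[a]
            zb = _zscore(work[[b]].astype(float))[b]
            work[name] = za * zb
            try:
                inter_fit = _fit(work, outcome, current + [name])
                p_int = float(inter_fit.pvalues[name])
            finally:
                work = work.drop(columns=[name])
            keep = p_int < alpha_interaction
            audit.append({
                "step": "interaction", "predictor": name,
                "p": p_int, "max_delta_beta": np.nan, "kept": keep,
            })
            if keep:
                interactions.append(name)
    return SelectionResult(tuple(current), tuple(interactions), tuple(audit))
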