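"""Random-intercept mixed models for movement-feature tables.

The study design is three-level: repeated observations (level 1) are
nested within participants (level 2), nested within experiment groups
(level 3).  For a feature index FI the models of interest are

    FI ~ sound_model + (1|group) + (1|participant)
    FI ~ sound_model + session + observation + (1|group) + (1|participant)

fitted by (restricted) maximum likelihood.  The module follows the
statsmodels model/results idiom: :class:`MovementFeatureModel` is built
from a feature table, ``fit()`` returns a :class:`MovementFeatureResults`
carrying fixed-effect estimates with standard errors, the three variance
components, the log-likelihood, Nakagawa-Schielzeth pseudo-R², Tukey-style
pairwise contrasts and likelihood-ratio tests against nested submodels.

The likelihood optimization itself is delegated to
:class:`statsmodels.regression.mixed_linear_model.MixedLM`; this module
owns the model construction (nesting structure, coding, inference
helpers), not the optimizer.

Conventions: likelihood-ratio tests compare ML fits; reported
coefficients come from REML fits.  ``sound_model`` uses treatment coding
with S1 as reference.  Participant labels are treated as unique within
group (purely nested design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.formula.api as smf

__all__ = [
    "MixedModelSpec",
    "MovementFeatureModel",
    "MovementFeatureResults",
    "fit_mixed",
    "lr_test",
    "pseudo_r2",
    "pairwise_contrasts",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MixedModelSpec:
    """Which response and fixed effects enter the model.

    ``fixed`` is any subset of {"sound_model", "session",
    "observation_number"}; the random part is always the nested
    group/participant intercepts.
    """

    response: str = "value"
    fixed: tuple = ("sound_model",)
    random_intercepts: tuple = ("group_id", "participant_id")

    _ALLOWED = ("sound_model", "session", "observation_number")

    def __post_init__(self) -> None:
        bad = set(self.fixed) - set(self._ALLOWED)
        if bad:
            raise ValueError(f"unsupported fixed effects: {sorted(bad)}")
        if not self.random_intercepts:
            raise ValueError("at least one random intercept is required")

    @property
    def formula_rhs(self) -> str:
        terms = []
        for f in self.fixed:
            terms.append("C(sound_model, Treatment('S1'))"
                         if f == "sound_model" else f)
        return " + ".join(terms) if terms else "1"

    def drop(self, term: str) -> "MixedModelSpec":
        """Nested spec with one fixed effect removed (for LR tests)."""
        if term not in self.fixed:
            raise ValueError(f"{term!r} not in fixed effects")
        return MixedModelSpec(self.response,
                              tuple(f for f in self.fixed if f != term),
                              self.random_intercepts)


class MovementFeatureModel:
    """Random-intercept LMM for one movement feature.

    Parameters
    ----------
    data : DataFrame
        One row per observation with the response column and the design
        labels ``sound_model``, ``participant_id``, ``group_id``,
        ``session``, ``observation_number``.
    spec : MixedModelSpec
        Response name and fixed-effect subset.
    """

    def __init__(self, data: pd.DataFrame, spec: MixedModelSpec):
        self.spec = spec
        need = {spec.response, "group_id", "participant_id"} | set(spec.fixed)
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        data = data.dropna(subset=[spec.response]).reset_index(drop=True)
        if data[spec.response].nunique() < 2:
            raise ValueError("response is constant; nothing to model")
        if data["group_id"].nunique() < 1:
            raise ValueError("no groups present")
        self.data = data
        self._single_group = data["group_id"].nunique() < 2

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, response: str,
                           fixed=("sound_model",)) -> "MovementFeatureModel":
        return cls(table, MixedModelSpec(response=response, fixed=tuple(fixed)))

    def _build(self):
        formula = f"Q('{self.spec.response}') ~ {self.spec.formula_rhs}"
        if self._single_group:
            # one group: the group intercept is confounded with the grand
            # mean and its variance unidentifiable; fit participants only
            return smf.mixedlm(formula, self.data,
                               groups=self.data["participant_id"],
                               re_formula="1")
        # participant intercepts enter as a variance component within the
        # group factor, giving the purely nested two-level random part
        vc = {"participant": "0 + C(participant_id)"}
        return smf.mixedlm(formula, self.data, groups=self.data["group_id"],
                           re_formula="1", vc_formula=vc)

    def fit(self, method: str = "reml") -> "MovementFeatureResults":
        """Fit by REML (default, for reporting) or ML (for LR tests)."""
        reml = method.lower() == "reml"
        if method.lower() not in ("reml", "ml"):
            raise ValueError("method must be 'REML' or 'ML'")
        mod = self._build()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit(reml=reml, method=["lbfgs", "powell"], maxiter=2000)
            if not np.isfinite(res.llf):
                # lbfgs can silently degenerate on small balanced designs
                res = mod.fit(reml=reml, method="bfgs", maxiter=2000)
        converged = bool(getattr(res, "converged", True))
        if not converged:
            warnings.warn("mixed-model fit did not converge; estimates are "
                          "reported with diagnostics", ConvergenceWarning)

        if self._single_group:
            var_group = 0.0
            var_participant = float(res.cov_re.iloc[0, 0])
            warnings.warn("single group: group variance unidentifiable, "
                          "estimated at the boundary 0", ConvergenceWarning)
        else:
            var_group = float(res.cov_re.iloc[0, 0])
            var_participant = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        var_residual = float(res.scale)

        k_fe = res.k_fe
        beta = res.fe_params.iloc[:k_fe]
        bse = res.bse.iloc[:k_fe]
        cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
        return MovementFeatureResults(
            model=self, method="REML" if reml else "ML",
            beta=beta, bse=bse, cov_beta=cov,
            var_group=max(var_group, 0.0),
            var_participant=max(var_participant, 0.0),
            var_residual=var_residual,
            loglik=float(res.llf), n_obs=int(res.nobs),
            converged=converged, _sm_result=res,
        )


@dataclass
class MovementFeatureResults:
    """Fitted random-intercept model: estimates, variances, inference."""

    model: MovementFeatureModel
    method: str
    beta: pd.Series
    bse: pd.Series
    cov_beta: np.ndarray
    var_group: float
    var_participant: float
    var_residual: float
    loglik: float
    n_obs: int
    converged: bool
    _sm_result: object = field(repr=False, default=None)

    @property
    def sd_group(self) -> float:
        return float(np.sqrt(self.var_group))

    @property
    def sd_participant(self) -> float:
        return float(np.sqrt(self.var_participant))

    @property
    def sd_residual(self) -> float:
        return float(np.sqrt(self.var_residual))

    @property
    def df_fixed(self) -> int:
        return len(self.beta)

    # -- pseudo-R² ---------------------------------------------------------
    def fixed_effect_variance(self) -> float:
        """Population variance of the fixed-effect linear predictor."""
        X = np.asarray(self._sm_result.model.exog)
        return float(np.var(X @ self.beta.to_numpy()))

    def pseudo_r2(self) -> tuple[float, float]:
        """Marginal and conditional R² (variance-partition form).

        marginal = var(Xb) / (var(Xb) + var_group + var_participant +
        var_residual); conditional adds both random-intercept variances to
        the numerator.  Conditional >= marginal by construction.
        """
        vf = self.fixed_effect_variance()
        vre = self.var_group + self.var_participant
        total = vf + vre + self.var_residual
        if total <= 0:
            raise ValueError("degenerate variance total")
        return vf / total, (vf + vre) / total

    # -- LR test -----------------------------------------------------------
    def lr_test(self, null: "MovementFeatureResults"
                ) -> tuple[float, int, float]:
        """Likelihood-ratio test against a nested null fit.

        Both fits must be ML (REML likelihoods are not comparable across
        fixed-effect structures).  Returns (chi2, df, p).
        """
        if self.method != "ML" or null.method != "ML":
            raise ValueError("LR tests require ML fits on both sides")
        if not set(null.beta.index) <= set(self.beta.index):
            raise ValueError("null model is not nested in the full model")
        df = self.df_fixed - null.df_fixed
        if df < 0:
            raise ValueError("null model has more parameters than the full")
        chi2 = max(2.0 * (self.loglik - null.loglik), 0.0)
        p = 1.0 if df == 0 else float(sstats.chi2.sf(chi2, df))
        return chi2, df, p

    # -- contrasts ---------------------------------------------------------
    def pairwise_contrasts(self, factor: str = "sound_model") -> pd.DataFrame:
        """All pairwise differences of the factor-level estimates.

        Multiplicity is adjusted with the studentized-range (Tukey)
        family: p = P(q_{k,df} > sqrt(2) |t|).  Estimates are exact
        differences of the fixed-effect coefficients under treatment
        coding.
        """
        if factor != "sound_model" or "sound_model" not in self.model.spec.fixed:
            raise ValueError(f"factor {factor!r} not among the fixed effects")
        names = list(self.beta.index)
        lvl_of = {}
        for i, n in enumerate(names):
            if "sound_model" in n and "T." in n:
                lvl_of[n.split("T.")[-1].rstrip("]")] = i
        levels = ["S1"] + sorted(lvl_of)
        k = len(levels)
        df_err = max(self.n_obs - self.df_fixed, 2)

        def coef_vec(level):
            v = np.zeros(len(names))
            if level in lvl_of:
                v[lvl_of[level]] = 1.0
            return v

        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                c = coef_vec(levels[j]) - coef_vec(levels[i])
                est = float(c @ self.beta.to_numpy())
                se = float(np.sqrt(c @ self.cov_beta @ c))
                tval = est / se if se > 0 else np.nan
                p = float(sstats.studentized_range.sf(
                    np.sqrt(2.0) * abs(tval), k, df_err))
                rows.append((f"{levels[j]} - {levels[i]}", est, se, tval, p))
        return pd.DataFrame(rows, columns=["pair", "estimate", "SE", "t",
                                           "p_tukey"])

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Random-intercept mixed model ({self.method}), "
            f"response = {self.model.spec.response}",
            f"n_obs = {self.n_obs}, log-likelihood = {self.loglik:.3f}, "
            f"converged = {self.converged}",
            "",
            f"{'Fixed effects':<42}{'coef':>10}{'SE':>10}",
        ]
        for name in self.beta.index:
            lines.append(f"{name:<42}{self.beta[name]:>10.4f}"
                         f"{self.bse[name]:>10.4f}")
        lines += [
            "",
            "Random effects (SD): "
            f"group = {self.sd_group:.4f}, "
            f"participant = {self.sd_participant:.4f}, "
            f"residual = {self.sd_residual:.4f}",
        ]
        try:
            r2m, r2c = self.pseudo_r2()
            lines.append(f"Pseudo-R2: marginal = {r2m:.4f}, "
                         f"conditional = {r2c:.4f}")
        except ValueError:
            pass
        return "\n".join(lines)


# -- functional conveniences (thin wrappers over the model objects) --------

def fit_mixed(table: pd.DataFrame, spec: MixedModelSpec,
              method: str = "REML") -> MovementFeatureResults:
    """Fit the random-intercept model described by ``spec`` on ``table``."""
    return MovementFeatureModel(table, spec).fit(method=method)


def lr_test(full: MovementFeatureResults, null: MovementFeatureResults):
    return full.lr_test(null)


def pseudo_r2(fit: MovementFeatureResults, table=None):
    return fit.pseudo_r2()


def pairwise_contrasts(fit: MovementFeatureResults, factor: str = "sound_model"):
    return fit.pairwise_contrasts(factor)
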