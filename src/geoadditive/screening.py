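"""Pre-modelling pipeline: anaemia classification, weighted prevalence,
univariate screening at the 10% level, and VIF collinearity checks.

Prevalence estimates are weighted by the survey sampling weights; their
95% confidence intervals use a logit-scale Wald construction with the
effective sample size n_eff = (sum w)^2 / sum w^2, which keeps the bounds
inside (0, 100).  Univariate screening fits one maximum-likelihood
logistic regression per covariate (unweighted) and applies a
likelihood-ratio test against the intercept-only model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .design import CATEGORY_LEVELS

ANAEMIA_HB_CUTOFF = 11.0  # g/dL; strictly below counts as anaemic


def classify_anaemia(hb_adjusted_gdl):
    """1 iff altitude-adjusted Hb is strictly below 11 g/dL (WHO, 6-59 months)."""
    hb = np.asarray(hb_adjusted_gdl, dtype=float)
    if np.any(hb <= 0):
        raise ValueError("haemoglobin must be positive")
    out = (hb < ANAEMIA_HB_CUTOFF).astype(int)
    return int(out) if np.isscalar(hb_adjusted_gdl) or hb.ndim == 0 else out


def _logit_wald_ci(phat: float, n_eff: float, level: float = 0.95):
    z = norm.ppf(0.5 + level / 2.0)
    tail = (1.0 - level) / 2.0
    if phat <= 0.0:  # Clopper-Pearson style bound at the boundary
        return 0.0, 1.0 - tail ** (1.0 / max(n_eff, 1.0))
    if phat >= 1.0:
        return tail ** (1.0 / max(n_eff, 1.0)), 1.0
    logit = np.log(phat / (1.0 - phat))
    se = np.sqrt(1.0 / (n_eff * phat * (1.0 - phat)))
    lo, hi = logit - z * se, logit + z * se
    return 1.0 / (1.0 + np.exp(-lo)), 1.0 / (1.0 + np.exp(-hi))


def weighted_prevalence(
    children: pd.DataFrame,
    by=None,
    outcome: str = "anaemic",
    weight: str = "survey_weight",
    level: float = 0.95,
) -> pd.DataFrame:
    """Survey-weighted prevalence (%) with CIs, optionally by grouping columns."""
    w = children[weight].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("survey weights must be positive")

    def one(group: pd.DataFrame, label) -> dict:
        gw = group[weight].to_numpy(dtype=float)
        gy = group[outcome].to_numpy(dtype=float)
        W = gw.sum()
        phat = float((gw * gy).sum() / W)
        n_eff = W**2 / (gw**2).sum()
        lo, hi = _logit_wald_ci(phat, n_eff, level)
        return {
            "group": label,
            "weighted_n": W,
            "prevalence_pct": 100.0 * phat,
            "ci_lo_pct": 100.0 * lo,
            "ci_hi_pct": 100.0 * hi,
        }

    if by is None:
        rows = [one(children, "overall")]
    else:
        by = [by] if isinstance(by, str) else list(by)
        rows = [
            one(group, key if len(by) > 1 else key)
            for key, group in children.groupby(by if len(by) > 1 else by[0], sort=True)
        ]
    return pd.DataFrame(rows)


def _encode_single(children: pd.DataFrame, covariate: str) -> np.ndarray:
    col = children[covariate]
    if covariate in CATEGORY_LEVELS or col.dtype == object:
        levels = list(CATEGORY_LEVELS.get(covariate, sorted(col.astype(str).unique())))
        present = [lv for lv in levels if (col.astype(str) == lv).any()]
        return np.column_stack([(col.astype(str) == lv).astype(float) for lv in present[1:]])
    return col.to_numpy(dtype=float)[:, None]


def univariate_screen(
    children: pd.DataFrame, covariates, alpha: float = 0.10, outcome: str = "anaemic"
) -> pd.DataFrame:
    """Likelihood-ratio screen of each covariate alone against the outcome.

    A covariate is retained when its LR p-value is below ``alpha``.
    Complete separation is flagged; the covariate is kept with a warning
    rather than dropped.
    """
    y = children[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must have both classes present")
    ll_null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    rows = []
    for cov in covariates:
        X = sm.add_constant(_encode_single(children, cov))
        separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.abs(res.params).max() > 15:
                separated = True
            lr = 2.0 * (res.llf - ll_null)
            p = float(chi2.sf(max(lr, 0.0), df=X.shape[1] - 1))
        except Exception:
            separated = True
            p = 0.0
        if separated:
            warnings.warn(
                f"possible complete separation for {cov!r}; kept with p set to 0",
                stacklevel=2,
            )
            p = 0.0
        include = bool(p < alpha) if alpha < 1.0 else True
        if alpha <= 0.0:
            include = False
        rows.append(
            {"covariate": cov, "p_value": p, "include": include, "separation_flag": separated}
        )
    return pd.DataFrame(rows)


def vif(children: pd.DataFrame, continuous_covariates, flag_at: float = 4.0) -> pd.DataFrame:
    """Variance inflation factors among the continuous covariates.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression of covariate j on the
    others (with intercept); a single covariate has VIF 1 by convention.
    """
    covs = list(continuous_covariates)
    Z = children[covs].to_numpy(dtype=float)
    if np.any(Z.std(axis=0) == 0):
        raise ValueError("constant covariate in VIF computation")
    rows = []
    for j, cov in enumerate(covs):
        if len(covs) == 1:
            v = 1.0
        else:
            yj = Z[:, j]
            Xj = np.column_stack([np.ones(len(Z)), np.delete(Z, j, axis=1)])
            resid = yj - Xj @ np.linalg.lstsq(Xj, yj, rcond=None)[0]
            ss_tot = ((yj - yj.mean()) ** 2).sum()
            r2 = 1.0 - (resid**2).sum() / ss_tot
            v = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        rows.append({"covariate": cov, "vif": v, "collinear_flag": bool(v >= flag_at)})
    return pd.DataFrame(rows)
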