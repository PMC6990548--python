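"""Shared fixed-effect encoding for the anaemia covariate set.

The covariates and reference levels mirror the standard childhood-anaemia
risk-factor set: child gender and malaria RDT result, household size and
composition, residence, mother's education, head-of-household gender,
toilet facility, wealth index, and the cluster-level environmental
covariates (altitude in 100 m units, EVI, day land-surface temperature).
Categorical terms are dummy coded against the stated reference level;
continuous terms enter linearly and unstandardised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Term:
    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple = ()
    reference: str = ""


CATEGORY_LEVELS = {
    "gender": ("male", "female"),
    "malaria_rdt": ("negative", "positive"),
    "residence": ("urban", "rural"),
    "mother_education": ("none", "primary", "secondary+", "unknown"),
    "head_gender": ("male", "female"),
    "toilet": ("none", "pit_latrine", "flush", "other"),
}

#: The multivariable fixed-effect set (child age excluded; it is either a
#: linear term in the GLM or a P-spline smooth in the additive models).
DEFAULT_TERMS: tuple[Term, ...] = (
    Term("gender", "categorical", CATEGORY_LEVELS["gender"], "male"),
    Term("malaria_rdt", "categorical", CATEGORY_LEVELS["malaria_rdt"], "negative"),
    Term("household_size", "continuous"),
    Term("residence", "categorical", CATEGORY_LEVELS["residence"], "urban"),
    Term("mother_education", "categorical", CATEGORY_LEVELS["mother_education"], "none"),
    Term("head_gender", "categorical", CATEGORY_LEVELS["head_gender"], "male"),
    Term("toilet", "categorical", CATEGORY_LEVELS["toilet"], "none"),
    Term("wealth_index", "continuous"),
    Term("cluster_altitude_100m", "continuous"),
    Term("evi", "continuous"),
    Term("lst", "continuous"),
)

AGE_TERM = Term("age_months", "continuous")


def column_name(term: Term, level: str | None = None) -> str:
    return term.name if level is None else f"{term.name}={level}"


def fixed_effects_matrix(
    df: pd.DataFrame,
    terms=DEFAULT_TERMS,
    intercept: bool = True,
    drop_empty_levels: bool = False,
):
    """Encode the fixed-effect design matrix.

    Returns ``(X, names)`` with an optional leading intercept column.
    Non-reference levels absent from the data are dropped with a warning
    when ``drop_empty_levels`` is set (model fitting); otherwise the full
    dummy encoding is kept (forward simulation).
    """
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for term in terms:
        if term.name not in df.columns:
            raise ValueError(f"covariate {term.name!r} missing from the child table")
        if term.kind == "continuous":
            cols.append(df[term.name].to_numpy(dtype=float))
            names.append(term.name)
            continue
        values = df[term.name].astype(str)
        unknown = set(values.unique()) - set(term.levels)
        if unknown:
            raise ValueError(f"unknown {term.name!r} levels {sorted(unknown)}")
        for level in term.levels:
            if level == term.reference:
                continue
            dummy = (values == level).to_numpy(dtype=float)
            if drop_empty_levels and not dummy.any():
                warnings.warn(
                    f"level {level!r} of {term.name!r} absent from data; column dropped",
                    stacklevel=2,
                )
                continue
            cols.append(dummy)
            names.append(column_name(term, level))
    return np.column_stack(cols), names
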