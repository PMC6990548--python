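"""DIC model comparison and hyper-prior sensitivity analysis.

DIC = Dbar + pD with pD = Dbar - D(theta_bar): Dbar is the posterior mean
of the deviance and D(theta_bar) the deviance at the posterior mean of the
linear predictor.  The model with the smallest DIC is preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import MCMCConfig, ModelSpec, PosteriorFit, PriorConfig, build_design
from .model import deviance as model_deviance
from .model import fit as model_fit


@dataclass(frozen=True)
class DICResult:
    dic: float
    p_d: float
    dbar: float
    d_hat: float


def dic(fit: PosteriorFit, children: pd.DataFrame | None = None) -> DICResult:
    """DIC, effective parameters pD, posterior-mean deviance and plug-in deviance."""
    draws, d_hat = model_deviance(fit, children)
    dbar = float(draws.mean())
    p_d = dbar - d_hat
    if p_d < 0:
        warnings.warn(f"negative effective number of parameters (pD = {p_d:.3f})", stacklevel=2)
    return DICResult(dic=dbar + p_d, p_d=p_d, dbar=dbar, d_hat=d_hat)


def compare(fits: dict | list, names=None) -> pd.DataFrame:
    """Rank fitted models by DIC (ascending).

    All fits must have been trained on the same rows; a data-hash check
    refuses cross-data comparisons.
    """
    if isinstance(fits, dict):
        names, fits = list(fits.keys()), list(fits.values())
    elif names is None:
        names = [f.spec.model_class for f in fits]
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash.split("|")[0] for f in fits}
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1 or len({f.y.tobytes() for f in fits}) > 1:
        raise ValueError("fits were trained on different data; refusing to compare")
    rows = []
    for name, f in zip(names, fits):
        r = dic(f)
        rows.append({"model": name, "DIC": r.dic, "pD": r.p_d, "Dbar": r.dbar, "Dhat": r.d_hat})
    table = pd.DataFrame(rows).sort_values("DIC", ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def sensitivity(
    children: pd.DataFrame,
    graph,
    spec: ModelSpec,
    hyper_grid=((1.0, 0.001), (1.0, 0.01), (0.5, 0.0005)),
    mcmc: MCMCConfig | None = None,
    priors: PriorConfig | None = None,
):
    """Refit under each (a, b) hyper-parameter setting and summarise drift.

    Returns ``(table, max_rel_change)``: one row per setting with the
    posterior-mean odds ratios and precision components, and the maximum
    relative change of any reported quantity against the first setting.
    """
    from .reporting import aor_table

    hyper_grid = list(hyper_grid)
    if not hyper_grid:
        raise ValueError("hyper_grid must be non-empty")
    priors = priors or PriorConfig()
    mm = build_design(children, spec, graph)
    rows = []
    for a, b in hyper_grid:
        f = model_fit(mm, replace(priors, hyper_a=a, hyper_b=b), mcmc)
        row = {"hyper_a": a, "hyper_b": b}
        aors = aor_table(f)
        for _, r in aors.iterrows():
            row[f"AOR:{r['term']}"] = r["aor"]
        for name, draws in f.tau2.items():
            row[f"tau2:{name}"] = float(draws.mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    quantities = [c for c in table.columns if c.startswith(("AOR:", "tau2:"))]
    if len(table) == 1:
        return table, 0.0
    base = table.iloc[0][quantities].astype(float)
    rel = ((table[quantities] - base).abs() / base.abs()).to_numpy()
    return table, float(np.nanmax(rel))
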