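"""Posterior summaries: AOR tables, variance components, smooth curves,
and per-district spatial-effect classification with map export.

All intervals are equal-tailed 95% credible intervals (2.5/97.5
percentiles of the draws).  A fixed effect is starred significant when
its AOR interval excludes 1; a district effect when its interval
excludes 0.  The AOR point estimate is the posterior mean of exp(beta)
(configurable to exp of the posterior mean).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .model import PosteriorFit


def _cri(draws: np.ndarray, level: float = 0.95, axis: int = 0):
    tail = 100.0 * (1.0 - level) / 2.0
    return (
        np.percentile(draws, tail, axis=axis),
        np.percentile(draws, 100.0 - tail, axis=axis),
    )


def _term_labels(fit: PosteriorFit, name: str):
    for term in fit.spec.fixed_terms:
        if name == term.name:
            return term.name, "", ""
        if name.startswith(term.name + "="):
            return term.name, name.split("=", 1)[1], term.reference
    return name, "", ""


def aor_table(fit: PosteriorFit, point: str = "mean_exp", level: float = 0.95) -> pd.DataFrame:
    """Adjusted posterior odds ratios with credible intervals; intercept excluded."""
    rows = []
    for j, name in enumerate(fit.fixed_names):
        if name == "intercept":
            continue
        odds = np.exp(fit.beta[:, j])
        # interval on the coefficient scale, then exponentiated (quantiles
        # are equivariant under monotone maps; keeps reciprocity exact)
        b_lo, b_hi = _cri(fit.beta[:, j], level)
        lo, hi = np.exp(b_lo), np.exp(b_hi)
        est = float(odds.mean()) if point == "mean_exp" else float(np.exp(fit.beta[:, j].mean()))
        variable, lev, ref = _term_labels(fit, name)
        rows.append(
            {
                "term": name,
                "variable": variable,
                "level": lev,
                "reference": ref,
                "aor": est,
                "cri_lo": float(lo),
                "cri_hi": float(hi),
                "significant": bool(lo > 1.0 or hi < 1.0),
            }
        )
    return pd.DataFrame(rows)


def variance_table(fit: PosteriorFit, level: float = 0.95):
    """Posterior precision components with CrIs and a dominance note.

    The spatial component with the LOWER precision (larger variance) is
    the dominant one.  Returns ``(table, note)``; the note is None unless
    both spatial components are present.
    """
    rows = []
    for name, draws in fit.tau2.items():
        lo, hi = _cri(draws, level)
        label = {
            "str": "structured spatial effect",
            "unstr": "unstructured spatial effect",
        }.get(name, name.replace("smooth:", "non-linear effect of "))
        rows.append(
            {"effect": label, "tau2_mean": float(draws.mean()), "cri_lo": float(lo), "cri_hi": float(hi)}
        )
    table = pd.DataFrame(rows)
    note = None
    if "str" in fit.tau2 and "unstr" in fit.tau2:
        t_str = float(fit.tau2["str"].mean())
        t_unstr = float(fit.tau2["unstr"].mean())
        dominant = "unstructured" if t_unstr < t_str else "structured"
        note = (
            f"the {dominant} spatial effect is dominant "
            f"(tau2_str = {t_str:.2f}, tau2_unstr = {t_unstr:.2f})"
        )
    return table, note


def smooth_summary(fit: PosteriorFit, covariate: str, grid=None, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and band of the centred smooth on a covariate grid."""
    if covariate not in fit.smooth_meta:
        raise ValueError(f"no smooth term for {covariate!r}")
    basis = fit.smooth_meta[covariate]
    if grid is None:
        lo, hi = basis.span
        grid = np.linspace(lo, hi, 101)
    grid = np.asarray(grid, dtype=float)
    from .smooth_basis import bspline_design

    curves = fit.alpha[covariate] @ bspline_design(grid, basis).T  # S x g
    band_lo, band_hi = _cri(curves, level)
    return pd.DataFrame(
        {covariate: grid, "mean": curves.mean(axis=0), "cri_lo": band_lo, "cri_hi": band_hi}
    )


def district_summary(fit: PosteriorFit, level: float = 0.95):
    """Per-district posterior summaries and significance classes.

    Returns ``(table, info)``: one row per district and component with
    mean, CrI and class in {significantly_positive, significantly_negative,
    null}; ``info`` holds class counts and the min/max posterior means per
    component.
    """
    if not fit.spec.spatial:
        raise ValueError("district summaries require a spatial (M3) fit")
    rows = []
    info = {}
    for comp, draws in (("structured", fit.f_str), ("unstructured", fit.f_unstr)):
        lo, hi = _cri(draws, level)
        means = draws.mean(axis=0)
        classes = np.where(lo > 0, "significantly_positive", np.where(hi < 0, "significantly_negative", "null"))
        for i, d in enumerate(fit.districts):
            rows.append(
                {
                    "district_id": d,
                    "component": comp,
                    "mean": float(means[i]),
                    "cri_lo": float(lo[i]),
                    "cri_hi": float(hi[i]),
                    "class": classes[i],
                }
            )
        info[comp] = {
            "significantly_positive": int((classes == "significantly_positive").sum()),
            "significantly_negative": int((classes == "significantly_negative").sum()),
            "null": int((classes == "null").sum()),
            "min_mean": float(means.min()),
            "max_mean": float(means.max()),
        }
    return pd.DataFrame(rows), info


def export_district_summaries(
    summaries: pd.DataFrame, out_csv, polygons_geojson=None, out_geojson=None
) -> None:
    """Write district summaries as CSV and, when polygons are given, GeoJSON.

    Polygon features are matched on ``properties.id``; features with no
    matching summary are flagged ``no_data`` (hatched districts on the
    maps).
    """
    summaries.to_csv(out_csv, index=False)
    if polygons_geojson is None:
        return
    with open(polygons_geojson, encoding="utf-8") as fh:
        gj = json.load(fh)
    by_district = {
        (str(d), comp): row
        for (d, comp), row in summaries.set_index(["district_id", "component"]).iterrows()
    }
    components = summaries["component"].unique()
    for feat in gj["features"]:
        props = feat.setdefault("properties", {})
        fid = str(props.get("id"))
        matched = False
        for comp in components:
            row = by_district.get((fid, comp))
            if row is None:
                continue
            matched = True
            prefix = {"structured": "str", "unstructured": "unstr"}.get(comp, comp)
            props[f"{prefix}_mean"] = float(row["mean"])
            props[f"{prefix}_cri_lo"] = float(row["cri_lo"])
            props[f"{prefix}_cri_hi"] = float(row["cri_hi"])
            props[f"{prefix}_class"] = str(row["class"])
        props["no_data"] = not matched
    with open(out_geojson or str(out_csv) + ".geojson", "w", encoding="utf-8") as fh:
        json.dump(gj, fh)
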