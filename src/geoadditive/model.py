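"""Bayesian geoadditive logistic regression fitted by Pólya-Gamma Gibbs sampling.

The linear predictor is

    logit(pi_hijk) = x'_hijk beta + f_age(age_hijk) + f_str(s_h) + f_unstr(s_h)

with vague N(0, 1000) priors on the fixed effects, a random-walk P-spline
prior on the smooth coefficients (precision tau2_r * K), the intrinsic CAR
prior on the structured district effect (precision tau2_str * Q) and iid
Gaussian priors on the unstructured effect (precision tau2_unstr * I).
Each precision carries a Gamma(a, b) hyperprior, a = 1, b = 0.001.

Inference augments each Bernoulli observation with a Pólya-Gamma variable
omega_i ~ PG(1, eta_i), which renders the full latent Gaussian block
(beta, alpha, f_str, f_unstr) conditionally Gaussian and the precisions
conditionally Gamma.  Identifiability constraints are built in exactly:
the smooth coefficients live in the subspace where the basis-column-mean
weighted sum is zero, the structured effect in the per-component
sum-to-zero eigen-subspace of Q, and the unstructured effect is recentred
into the intercept every sweep.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, null_space, solve_triangular

from ._pg import sample_pg
from .design import AGE_TERM, DEFAULT_TERMS, Term, fixed_effects_matrix
from .smooth_basis import (
    PenaltyMatrix,
    SplineBasisSpec,
    bspline_design,
    make_basis_spec,
    rw_penalty,
)
from .spatial_structure import AdjacencyGraph, icar_structure, sum_to_zero_basis

MODEL_CLASSES = ("m1_glm", "m2_gam", "m3_geoadditive")


@dataclass(frozen=True)
class PriorConfig:
    """Prior constants: fixed-effect variance and the Gamma(a, b) hyperprior."""

    beta_variance: float = 1000.0
    hyper_a: float = 1.0
    hyper_b: float = 0.001

    def __post_init__(self):
        if min(self.beta_variance, self.hyper_a, self.hyper_b) <= 0:
            raise ValueError("all prior constants must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 2000
    burn_in: int = 500
    thin: int = 1
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self):
        if self.burn_in < 0 or self.n_iter <= self.burn_in:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


@dataclass
class SmoothConfig:
    degree: int = 3
    n_inner: int = 17
    rw_order: int = 2


@dataclass
class ModelSpec:
    """Which terms enter the predictor for model classes M1/M2/M3."""

    model_class: str
    fixed_terms: tuple = DEFAULT_TERMS
    smooth_terms: dict = field(default_factory=dict)  # covariate -> SmoothConfig
    spatial: bool = False

    def __post_init__(self):
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"model_class must be one of {MODEL_CLASSES}")
        fixed_names = {t.name for t in self.fixed_terms}
        overlap = fixed_names & set(self.smooth_terms)
        if overlap:
            raise ValueError(f"covariates in both fixed and smooth terms: {sorted(overlap)}")
        if self.model_class == "m1_glm" and (self.smooth_terms or self.spatial):
            raise ValueError("M1 is a plain GLM: no smooth or spatial terms")
        if self.model_class == "m2_gam" and self.spatial:
            raise ValueError("M2 has no spatial term")
        if self.model_class == "m3_geoadditive" and not self.spatial:
            raise ValueError("M3 requires the spatial term")

    @classmethod
    def for_model(cls, which: str, n_inner: int = 17, degree: int = 3, rw_order: int = 2):
        """The three candidate models: GLM, GAM with a smooth age effect,
        and the geoadditive model adding the BYM spatial pair."""
        which = which.lower()
        smooth = {AGE_TERM.name: SmoothConfig(degree=degree, n_inner=n_inner, rw_order=rw_order)}
        if which in ("m1", "m1_glm"):
            return cls("m1_glm", fixed_terms=DEFAULT_TERMS + (AGE_TERM,))
        if which in ("m2", "m2_gam"):
            return cls("m2_gam", smooth_terms=smooth)
        if which in ("m3", "m3_geoadditive"):
            return cls("m3_geoadditive", smooth_terms=smooth, spatial=True)
        raise ValueError(f"unknown model {which!r}")


@dataclass
class SmoothBlock:
    covariate: str
    basis: SplineBasisSpec
    penalty: PenaltyMatrix
    B: np.ndarray = field(repr=False)  # n x M design
    T: np.ndarray = field(repr=False)  # M x (M-1) centering constraint basis
    S: np.ndarray = field(repr=False)  # T' K T (reparametrised prior structure)


@dataclass
class ModelMatrices:
    """Assembled design for one model on one data set."""

    spec: ModelSpec
    y: np.ndarray
    F: np.ndarray = field(repr=False)
    fixed_names: list = field(default_factory=list)
    smooths: dict = field(default_factory=dict)  # covariate -> SmoothBlock
    graph: AdjacencyGraph | None = None
    d_idx: np.ndarray | None = None  # per-row district index into graph.nodes
    V_str: np.ndarray | None = None  # ICAR sum-to-zero eigenbasis
    lam_str: np.ndarray | None = None
    icar_rank: int = 0
    data_hash: str = ""

    @property
    def n(self) -> int:
        return self.y.size


def _hash_data(y: np.ndarray, districts: np.ndarray | None) -> str:
    h = hashlib.sha256(np.ascontiguousarray(y, dtype=np.int8).tobytes())
    if districts is not None:
        h.update("|".join(map(str, districts)).encode())
    return h.hexdigest()[:16]


def build_design(
    children: pd.DataFrame, spec: ModelSpec, graph: AdjacencyGraph | None = None
) -> ModelMatrices:
    """Assemble outcome, fixed-effect, smooth and spatial design pieces.

    Rows with missing values in any used column are dropped with a logged
    count.  For spatial models every district in the data must appear in
    the adjacency graph.
    """
    used = ["anaemic"] + [t.name for t in spec.fixed_terms] + list(spec.smooth_terms)
    if spec.spatial:
        used.append("district_id")
    present = [c for c in used if c in children.columns]
    missing_cols = sorted(set(used) - set(present))
    if missing_cols:
        raise ValueError(f"child table missing columns {missing_cols}")
    complete = children[used].notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} rows with missing values", stacklevel=2)
        children = children.loc[complete]

    y = children["anaemic"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be 0/1")
    F, fixed_names = fixed_effects_matrix(
        children, spec.fixed_terms, intercept=True, drop_empty_levels=True
    )

    smooths = {}
    for cov, cfg in spec.smooth_terms.items():
        z = children[cov].to_numpy(dtype=float)
        basis = make_basis_spec(z, degree=cfg.degree, n_inner=cfg.n_inner)
        B = bspline_design(z, basis)
        penalty = rw_penalty(basis.n_basis, cfg.rw_order)
        w = B.mean(axis=0)  # centering: column-mean weighted coefficient sum is 0
        T = null_space(w[None, :])
        smooths[cov] = SmoothBlock(cov, basis, penalty, B, T, T.T @ penalty.K @ T)

    d_idx = V = lam = None
    rank = 0
    if spec.spatial:
        if graph is None:
            raise ValueError("spatial model requires an adjacency graph")
        idx = graph.index()
        unseen = sorted(set(children["district_id"].astype(str)) - set(map(str, graph.nodes)))
        if unseen:
            raise ValueError(f"districts absent from the adjacency graph: {unseen}")
        d_idx = children["district_id"].astype(str).map({str(k): v for k, v in idx.items()}).to_numpy()
        icar = icar_structure(graph)
        V, lam = sum_to_zero_basis(icar)
        rank = icar.rank

    districts = children["district_id"].to_numpy() if spec.spatial else None
    return ModelMatrices(
        spec=spec,
        y=y,
        F=F,
        fixed_names=fixed_names,
        smooths=smooths,
        graph=graph if spec.spatial else None,
        d_idx=d_idx,
        V_str=V,
        lam_str=lam,
        icar_rank=rank,
        data_hash=_hash_data(y, districts),
    )


@dataclass
class PosteriorFit:
    """Joint posterior draws, per-draw deviance, and the design used."""

    spec: ModelSpec
    priors: PriorConfig
    mcmc: MCMCConfig
    fixed_names: list
    beta: np.ndarray = field(repr=False)  # S x p
    alpha: dict = field(default_factory=dict, repr=False)  # covariate -> S x M
    smooth_meta: dict = field(default_factory=dict)  # covariate -> SplineBasisSpec
    districts: list | None = None
    f_str: np.ndarray | None = field(default=None, repr=False)  # S x n_districts
    f_unstr: np.ndarray | None = field(default=None, repr=False)
    tau2: dict = field(default_factory=dict, repr=False)  # name -> S draws
    deviance: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    eta_mean: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    data_hash: str = ""

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_obs(self) -> int:
        return self.y.size


def _sample_precision(rng, a: float, b: float, rank: int, quad: float, size=None):
    """Gamma full conditional for a precision: Gamma(a + rank/2, b + quad/2)."""
    return rng.gamma(a + rank / 2.0, 1.0 / (b + quad / 2.0), size=size)


def fit(mm: ModelMatrices, priors: PriorConfig | None = None, mcmc: MCMCConfig | None = None) -> PosteriorFit:
    """Gibbs sampler over (latent Gaussian block, PG variables, precisions)."""
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    y = mm.y
    n = mm.n
    kappa = y - 0.5

    # column layout: [fixed | smooth u-blocks | structured u | unstructured f]
    parts = [mm.F]
    slices = {"beta": slice(0, mm.F.shape[1])}
    pos = mm.F.shape[1]
    for cov, blk in mm.smooths.items():
        BT = blk.B @ blk.T
        parts.append(BT)
        slices[f"smooth:{cov}"] = slice(pos, pos + BT.shape[1])
        pos += BT.shape[1]
    if mm.spec.spatial:
        n_d = mm.graph.n
        parts.append(mm.V_str[mm.d_idx, :])
        slices["str"] = slice(pos, pos + mm.V_str.shape[1])
        pos += mm.V_str.shape[1]
        U = np.zeros((n, n_d))
        U[np.arange(n), mm.d_idx] = 1.0
        parts.append(U)
        slices["unstr"] = slice(pos, pos + n_d)
        pos += n_d
    X = np.hstack(parts)
    p = X.shape[1]
    Xt_kappa = X.T @ kappa
    i0 = mm.fixed_names.index("intercept")

    n_store_per_chain = (mcmc.n_iter - mcmc.burn_in + mcmc.thin - 1) // mcmc.thin
    S = n_store_per_chain * mcmc.n_chains
    store = {
        "theta": np.empty((S, p)),
        "tau2": {name: np.empty(S) for name in
                 [f"smooth:{c}" for c in mm.smooths] + (["str", "unstr"] if mm.spec.spatial else [])},
        "deviance": np.empty(S),
    }
    eta_sum = np.zeros(n)
    s = 0
    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(mcmc.seed), chain]))
        theta = np.zeros(p)
        tau2 = {name: 10.0 for name in store["tau2"]}
        eta = X @ theta
        for it in range(mcmc.n_iter):
            omega = sample_pg(eta, rng)
            A = X.T @ (X * omega[:, None])
            bsl = slices["beta"]
            A[np.arange(bsl.start, bsl.stop), np.arange(bsl.start, bsl.stop)] += 1.0 / priors.beta_variance
            for cov, blk in mm.smooths.items():
                sl = slices[f"smooth:{cov}"]
                A[sl, sl] += tau2[f"smooth:{cov}"] * blk.S
            if mm.spec.spatial:
                sl = slices["str"]
                A[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += tau2["str"] * mm.lam_str
                sl = slices["unstr"]
                A[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += tau2["unstr"]
            try:
                c_factor = cho_factor(A, lower=False, check_finite=False)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    "latent Gaussian update failed (possible separation or "
                    "degenerate design); posterior precision not positive definite"
                ) from exc
            mean = cho_solve(c_factor, Xt_kappa, check_finite=False)
            z = rng.standard_normal(p)
            theta = mean + solve_triangular(c_factor[0], z, lower=False, check_finite=False)
            if not np.all(np.isfinite(theta)):
                raise RuntimeError("non-finite draw in the latent block; check for separation")
            # recentre the unstructured effect into the intercept (the
            # smooth and structured blocks are centred exactly by the
            # reparametrisation)
            if mm.spec.spatial:
                f_u = theta[slices["unstr"]]
                shift = f_u.mean()
                theta[slices["unstr"]] = f_u - shift
                theta[i0] += shift
            # precision updates
            for cov, blk in mm.smooths.items():
                key = f"smooth:{cov}"
                u = theta[slices[key]]
                tau2[key] = _sample_precision(
                    rng, priors.hyper_a, priors.hyper_b, blk.penalty.rank, float(u @ blk.S @ u)
                )
            if mm.spec.spatial:
                u = theta[slices["str"]]
                tau2["str"] = _sample_precision(
                    rng, priors.hyper_a, priors.hyper_b, mm.icar_rank, float((mm.lam_str * u * u).sum())
                )
                f_u = theta[slices["unstr"]]
                tau2["unstr"] = _sample_precision(
                    rng, priors.hyper_a, priors.hyper_b, len(f_u), float(f_u @ f_u)
                )
            eta = X @ theta
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                store["theta"][s] = theta
                for name in tau2:
                    store["tau2"][name][s] = tau2[name]
                store["deviance"][s] = bernoulli_deviance(y, eta)
                eta_sum += eta
                s += 1
    assert s == S

    theta_draws = store["theta"]
    alpha = {}
    for cov, blk in mm.smooths.items():
        alpha[cov] = theta_draws[:, slices[f"smooth:{cov}"]] @ blk.T.T
    f_str = f_unstr = None
    districts = None
    if mm.spec.spatial:
        f_str = theta_draws[:, slices["str"]] @ mm.V_str.T
        f_unstr = theta_draws[:, slices["unstr"]]
        districts = list(mm.graph.nodes)
    return PosteriorFit(
        spec=mm.spec,
        priors=priors,
        mcmc=mcmc,
        fixed_names=list(mm.fixed_names),
        beta=theta_draws[:, slices["beta"]],
        alpha=alpha,
        smooth_meta={cov: blk.basis for cov, blk in mm.smooths.items()},
        districts=districts,
        f_str=f_str,
        f_unstr=f_unstr,
        tau2=store["tau2"],
        deviance=store["deviance"],
        eta_mean=eta_sum / S,
        y=y.astype(np.int8),
        data_hash=mm.data_hash,
    )


def fit_model(
    children: pd.DataFrame,
    model: str = "m3",
    graph: AdjacencyGraph | None = None,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
    **spec_kwargs,
) -> PosteriorFit:
    """Convenience wrapper: spec + design + Gibbs fit in one call."""
    spec = ModelSpec.for_model(model, **spec_kwargs)
    mm = build_design(children, spec, graph)
    return fit(mm, priors, mcmc)


def bernoulli_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """D = -2 sum[y log pi + (1-y) log(1-pi)] evaluated stably on the logit scale."""
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def linear_predictor(fit: PosteriorFit, children: pd.DataFrame):
    """Per-draw eta and pi for (possibly new) children under a fitted model.

    The fixed-effect encoding reuses the fitted column set; smooth values
    must lie within the fitted knot span; district effects are looked up
    per district.
    """
    F, names = fixed_effects_matrix(children, fit.spec.fixed_terms, intercept=True)
    cols = [names.index(c) for c in fit.fixed_names]
    eta = fit.beta @ F[:, cols].T
    for cov, basis in fit.smooth_meta.items():
        B = bspline_design(children[cov].to_numpy(dtype=float), basis)
        eta += fit.alpha[cov] @ B.T
    if fit.spec.spatial:
        idx = {str(d): i for i, d in enumerate(fit.districts)}
        try:
            d_idx = np.array([idx[str(d)] for d in children["district_id"]])
        except KeyError as exc:
            raise ValueError(f"district {exc.args[0]!r} not in the fitted graph") from None
        eta += fit.f_str[:, d_idx] + fit.f_unstr[:, d_idx]
    pi = 1.0 / (1.0 + np.exp(-eta))
    return eta, pi


def deviance(fit: PosteriorFit, children: pd.DataFrame | None = None):
    """Per-draw deviance D(theta) and the plug-in D(theta_bar).

    With no ``children`` the training-data quantities stored in the fit
    are used; D(theta_bar) evaluates the deviance at the posterior mean
    of the linear predictor (plug-in on the predictor scale).
    """
    if children is None:
        return fit.deviance, bernoulli_deviance(fit.y.astype(float), fit.eta_mean)
    y = children["anaemic"].to_numpy(dtype=float)
    eta, _ = linear_predictor(fit, children)
    draws = np.array([bernoulli_deviance(y, e) for e in eta])
    return draws, bernoulli_deviance(y, eta.mean(axis=0))


def save_fit(fit: PosteriorFit, out_dir) -> None:
    """Persist draws as CSV (one column per parameter) plus a JSON manifest."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = {name: fit.beta[:, j] for j, name in enumerate(fit.fixed_names)}
    for cov, draws in fit.alpha.items():
        for m in range(draws.shape[1]):
            frames[f"alpha:{cov}:{m}"] = draws[:, m]
    if fit.spec.spatial:
        for i, d in enumerate(fit.districts):
            frames[f"f_str:{d}"] = fit.f_str[:, i]
            frames[f"f_unstr:{d}"] = fit.f_unstr[:, i]
    for name, draws in fit.tau2.items():
        frames[f"tau2:{name}"] = draws
    frames["deviance"] = fit.deviance
    pd.DataFrame(frames).to_csv(out / "draws.csv", index=False)
    manifest = {
        "model_class": fit.spec.model_class,
        "fixed_names": fit.fixed_names,
        "smooth_basis": {cov: b.to_dict() for cov, b in fit.smooth_meta.items()},
        "districts": fit.districts,
        "priors": vars(fit.priors),
        "mcmc": vars(fit.mcmc),
        "data_hash": fit.data_hash,
        "n_obs": int(fit.n_obs),
        "eta_mean": fit.eta_mean.tolist(),
        "y": fit.y.astype(int).tolist(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest))


def load_fit(out_dir) -> PosteriorFit:
    import pathlib

    out = pathlib.Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    draws = pd.read_csv(out / "draws.csv")
    spec = ModelSpec.for_model(manifest["model_class"].split("_")[0])
    smooth_meta = {
        cov: SplineBasisSpec.from_dict(d) for cov, d in manifest["smooth_basis"].items()
    }
    beta = draws[manifest["fixed_names"]].to_numpy()
    alpha = {}
    for cov, basis in smooth_meta.items():
        cols = [f"alpha:{cov}:{m}" for m in range(basis.n_basis)]
        alpha[cov] = draws[cols].to_numpy()
    districts = manifest["districts"]
    f_str = f_unstr = None
    if districts:
        f_str = draws[[f"f_str:{d}" for d in districts]].to_numpy()
        f_unstr = draws[[f"f_unstr:{d}" for d in districts]].to_numpy()
    tau2 = {
        c[len("tau2:"):]: draws[c].to_numpy() for c in draws.columns if c.startswith("tau2:")
    }
    return PosteriorFit(
        spec=spec,
        priors=PriorConfig(**manifest["priors"]),
        mcmc=MCMCConfig(**manifest["mcmc"]),
        fixed_names=manifest["fixed_names"],
        beta=beta,
        alpha=alpha,
        smooth_meta=smooth_meta,
        districts=districts,
        f_str=f_str,
        f_unstr=f_unstr,
        tau2=tau2,
        deviance=draws["deviance"].to_numpy(),
        eta_mean=np.asarray(manifest["eta_mean"]),
        y=np.asarray(manifest["y"], dtype=np.int8),
        data_hash=manifest["data_hash"],
    )
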