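"""Generalized linear mixed models with crossed random intercepts.

Maximum-likelihood estimation via the Laplace approximation: for candidate
variance parameters, the joint penalized likelihood is maximized over fixed
effects and random intercepts together (penalized iteratively reweighted
least squares), and the marginal likelihood is the joint value corrected by
the log-determinant of the random-effect curvature block.  Supports the
binomial-logit family for single-trial psychometric data and the
Poisson-log family for spike counts, Wald inference, AIC/likelihood-ratio
model comparison, variance-partition R-squared on the latent scale and
simulation-based randomized quantile residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.special import expit, gammaln


class ModelSpecError(ValueError):
    """Raised for an inconsistent model specification."""


class SeparationError(RuntimeError):
    """Raised when the fixed-effect design is (quasi-)completely separated."""


@dataclass
class ModelSpec:
    """Declarative GLMM structure.

    ``fixed`` lists main-effect column names; interactions are declared as
    ``"a:b"`` strings whose components must appear in ``fixed``.  ``random``
    lists grouping columns, each contributing one crossed random intercept.
    ``scale`` maps column names to ``"zscore"`` for standardization before
    fitting (recorded in the fit).
    """

    response: str
    family: str = "binomial"
    fixed: list[str] = field(default_factory=list)
    interactions: list[str] = field(default_factory=list)
    random: list[str] = field(default_factory=list)
    scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "poisson"):
            raise ModelSpecError(f"unsupported family {self.family!r}")
        for term in self.interactions:
            parts = term.split(":")
            if len(parts) < 2 or any(p not in self.fixed for p in parts):
                raise ModelSpecError(
                    f"interaction {term!r} must reference declared main effects"
                )

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class MixedModelFit:
    """Fitted GLMM: coefficient table, variance components, fit statistics."""

    spec: ModelSpec
    coef: pd.DataFrame
    re_sd: dict
    re_modes: dict
    loglik: float
    n_obs: int
    converged: bool
    gradient_norm: float
    scaling: dict
    _design: dict = field(default_factory=dict, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.coef) + len(self.re_sd)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def summary(self) -> str:
        lines = [
            f"GLMM ({self.spec.family}-{'logit' if self.spec.family == 'binomial' else 'log'}), "
            f"n = {self.n_obs}, logLik = {self.loglik:.2f}, AIC = {self.aic:.2f}",
            self.coef.to_string(float_format=lambda v: f"{v: .4f}"),
            "Random intercept SDs: "
            + ", ".join(f"{k} = {v:.4f}" for k, v in self.re_sd.items()),
        ]
        marg, cond = r2_mixed(self)
        lines.append(f"Marginal R2 = {marg:.4f}, Conditional R2 = {cond:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "n_obs": self.n_obs,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "coefficients": self.coef.reset_index().to_dict(orient="records"),
            "random_effect_sd": self.re_sd,
            "r2": dict(zip(("marginal", "conditional"), r2_mixed(self))),
        }


def _build_design(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[np.ndarray, list[str], list[sparse.csr_matrix], list[list], dict]:
    """Fixed design matrix, names, and one indicator block per grouping factor."""
    if spec.response not in data.columns:
        raise ModelSpecError(f"response column {spec.response!r} missing")
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    scaling: dict = {}
    main: dict[str, np.ndarray] = {}
    for term in spec.fixed:
        if term not in data.columns:
            raise ModelSpecError(f"fixed-effect column {term!r} missing")
        x = data[term]
        if x.dtype == object or x.dtype == bool or isinstance(x.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(x.astype(str)))
            ref = levels[0]
            for lev in levels[1:]:
                v = (x.astype(str) == lev).to_numpy(float)
                main[term] = v  # last non-reference level stands in interactions
                cols.append(v)
                names.append(f"{term}[{lev}]")
            scaling[term] = {"type": "dummy", "reference": ref}
            if len(levels) == 2:
                continue
        else:
            v = x.to_numpy(float)
            if spec.scale.get(term) == "zscore":
                mu, sd = v.mean(), v.std() or 1.0
                v = (v - mu) / sd
                scaling[term] = {"type": "zscore", "mean": mu, "sd": sd}
            main[term] = v
            cols.append(v)
            names.append(term)
    for term in spec.interactions:
        parts = term.split(":")
        v = np.ones(n)
        for p in parts:
            if p not in main:
                raise ModelSpecError(f"interaction component {p!r} unavailable")
            v = v * main[p]
        cols.append(v)
        names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelSpecError("fixed design is rank deficient")

    Zs, level_names = [], []
    for g in spec.random:
        if g not in data.columns:
            raise ModelSpecError(f"grouping column {g!r} missing")
        codes, levels = pd.factorize(data[g])
        if len(levels) < 2:
            raise ModelSpecError(f"grouping factor {g!r} needs >= 2 levels")
        Z = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
        )
        Zs.append(Z)
        level_names.append(list(levels))
    return X, names, Zs, level_names, scaling


def _family_funcs(family: str):
    if family == "binomial":
        def loglik(y, eta):
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

        def mu_w(eta):
            m = expit(eta)
            return m, m * (1.0 - m)
    else:  # poisson
        def loglik(y, eta):
            return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))

        def mu_w(eta):
            m = np.exp(np.clip(eta, -30, 30))
            return m, m
    return loglik, mu_w


def _pirls(
    y: np.ndarray,
    X: np.ndarray,
    Z: sparse.csr_matrix | None,
    prec: np.ndarray | None,
    family: str,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Joint Newton maximization of the penalized log-likelihood over (beta, b).

    ``prec`` holds the per-column prior precision (1/sigma^2) for the
    random-effect block; returns the mode, the penalized log-likelihood at
    the mode, and the gradient at convergence.
    """
    loglik, mu_w = _family_funcs(family)
    p = X.shape[1]
    q = Z.shape[1] if Z is not None else 0
    u = np.zeros(p + q) if start is None else start.copy()
    grad = np.zeros(p + q)

    def eta_of(u):
        eta = X @ u[:p]
        if q:
            eta = eta + Z @ u[p:]
        return eta

    def objective(u):
        pen = 0.5 * np.sum(prec * u[p:] ** 2) if q else 0.0
        return loglik(y, eta_of(u)) - pen

    obj = objective(u)
    for _ in range(max_iter):
        eta = eta_of(u)
        mu, w = mu_w(eta)
        r = y - mu
        grad[:p] = X.T @ r
        if q:
            grad[p:] = Z.T @ r - prec * u[p:]
        H = np.empty((p + q, p + q))
        Xw = X * w[:, None]
        H[:p, :p] = X.T @ Xw
        if q:
            ZtWX = Z.T @ Xw
            H[p:, :p] = ZtWX
            H[:p, p:] = ZtWX.T
            ZtWZ = (Z.multiply(w[:, None])).T @ Z
            H[p:, p:] = ZtWZ.toarray() + np.diag(prec)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p + q), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving line search
        t = 1.0
        for _ in range(30):
            new = u + t * step
            new_obj = objective(new)
            if new_obj >= obj - 1e-12:
                break
            t *= 0.5
        gain = new_obj - obj
        u, obj = new, new_obj
        if abs(gain) < tol * (abs(obj) + 1.0):
            break
    return u, obj, grad


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    tol: float = 1e-6,
    max_coef: float = 30.0,
    fixed_sd: dict | None = None,
) -> MixedModelFit:
    """Fit a GLMM by Laplace-approximated maximum likelihood.

    The outer optimization runs over the log random-intercept standard
    deviations; the inner penalized IRLS profiles fixed effects and random
    modes jointly.  ``fixed_sd`` pins named grouping factors to a given
    standard deviation instead of estimating them (zero collapses the model
    onto an ordinary GLM for that factor).  Raises
    :class:`SeparationError` when coefficients diverge (complete
    separation) and reports the gradient norm on non-convergence.
    """
    X, names, Zs, level_names, scaling = _build_design(spec, data)
    y = data[spec.response].to_numpy(float)
    if spec.family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ModelSpecError("binomial response must be 0/1")
    n, p = X.shape
    loglik_f, mu_w = _family_funcs(spec.family)
    if Zs:
        Z = sparse.hstack(Zs, format="csr")
        q_sizes = [z.shape[1] for z in Zs]
    else:
        Z, q_sizes = None, []
    q = sum(q_sizes)
    expand = np.repeat(np.arange(len(q_sizes)), q_sizes) if q_sizes else None

    fixed_sd = fixed_sd or {}
    free_idx = [i for i, g in enumerate(spec.random) if g not in fixed_sd]
    pinned = np.zeros(len(spec.random))
    for i, g in enumerate(spec.random):
        if g in fixed_sd:
            pinned[i] = np.log(max(float(fixed_sd[g]), 1e-4))

    state = {"u": None}

    def full_log_sd(free: np.ndarray) -> np.ndarray:
        out = pinned.copy()
        out[free_idx] = free
        return out

    def laplace_nll(log_sd: np.ndarray) -> float:
        sd = np.exp(log_sd)
        prec = (1.0 / sd[expand] ** 2) if q else None
        u, obj, _ = _pirls(y, X, Z, prec, spec.family, start=state["u"])
        state["u"] = u
        eta = X @ u[:p] + (Z @ u[p:] if q else 0.0)
        _, w = mu_w(eta)
        ZtWZ = (Z.multiply(w[:, None])).T @ Z if q else None
        ll = obj  # penalized joint log-likelihood at the mode
        if q:
            S = ZtWZ.toarray() + np.diag(prec)
            sign, logdet = np.linalg.slogdet(S)
            ll += -0.5 * logdet - np.sum(np.log(sd) * np.array(q_sizes))
        return -ll

    if q and free_idx:
        x0 = np.zeros(len(free_idx))
        res = optimize.minimize(
            lambda free: laplace_nll(full_log_sd(free)),
            x0,
            method="L-BFGS-B",
            bounds=[(-8.0, 3.0)] * len(free_idx),
            options={"ftol": tol * 1e-3, "gtol": tol},
        )
        log_sd = full_log_sd(res.x)
        loglik = -res.fun
        outer_ok = res.success or res.fun <= laplace_nll(full_log_sd(x0))
    elif q:
        log_sd = pinned
        loglik = -laplace_nll(log_sd)
        outer_ok = True
    else:
        log_sd = np.empty(0)
        loglik = -laplace_nll(log_sd)
        outer_ok = True

    sd = np.exp(log_sd)
    prec = (1.0 / sd[expand] ** 2) if q else None
    u, _, grad = _pirls(y, X, Z, prec, spec.family, start=state["u"])
    beta, b = u[:p], u[p:]
    if np.max(np.abs(beta)) > max_coef:
        raise SeparationError(
            "fixed-effect estimate diverged; the design is likely separated"
        )

    eta = X @ beta + (Z @ b if q else 0.0)
    _, w = mu_w(eta)
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    if q:
        ZtWX = Z.T @ Xw
        S = ((Z.multiply(w[:, None])).T @ Z).toarray() + np.diag(prec)
        cov_beta = np.linalg.inv(XtWX - ZtWX.T @ np.linalg.solve(S, ZtWX))
    else:
        cov_beta = np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": pvals}, index=names
    )
    gnorm = float(np.linalg.norm(grad))
    re_modes = {}
    off = 0
    for gname, levels, k in zip(spec.random, level_names, q_sizes):
        re_modes[gname] = dict(zip(levels, b[off: off + k]))
        off += k
    return MixedModelFit(
        spec=spec,
        coef=coef,
        re_sd=dict(zip(spec.random, sd)),
        re_modes=re_modes,
        loglik=float(loglik),
        n_obs=n,
        converged=bool(outer_ok and gnorm < 1e-3 * (1 + n)),
        gradient_norm=gnorm,
        scaling=scaling,
        _design={"X": X, "Zs": Zs, "y": y},
    )


def compare_models(fits: list[MixedModelFit]) -> pd.DataFrame:
    """AIC ranking plus likelihood-ratio tests for nested pairs.

    Fits must share the response and data; a pair is treated as nested when
    one fit's coefficient names are a subset of the other's, in which case
    the analysis-of-deviance chi-square p-value is reported against the
    smallest such super-model.
    """
    if len({f.n_obs for f in fits}) != 1:
        raise ValueError("fits must be on identical data")
    rows = []
    order = np.argsort([f.aic for f in fits])
    for rank, i in enumerate(order):
        f = fits[i]
        row = {
            "model": i,
            "terms": " + ".join(f.coef.index),
            "n_params": f.n_params,
            "loglik": f.loglik,
            "aic": f.aic,
            "delta_aic": f.aic - fits[order[0]].aic,
            "lrt_chi2": np.nan,
            "lrt_df": np.nan,
            "lrt_p": np.nan,
            "nested_in": np.nan,
        }
        supers = [
            j
            for j, g in enumerate(fits)
            if j != i
            and set(f.coef.index) < set(g.coef.index)
            and set(f.spec.random) <= set(g.spec.random)
        ]
        if supers:
            j = min(supers, key=lambda j: fits[j].n_params)
            g = fits[j]
            chi2 = 2.0 * (g.loglik - f.loglik)
            df = g.n_params - f.n_params
            row.update(
                lrt_chi2=chi2,
                lrt_df=df,
                lrt_p=stats.chi2.sf(max(chi2, 0.0), df),
                nested_in=j,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


def r2_mixed(fit: MixedModelFit) -> tuple[float, float]:
    """Latent-scale variance-partition R-squared (marginal, conditional).

    Marginal: variance of the fixed-effect predictor over the sum of fixed,
    random and distribution-specific variance (pi^2/3 for the logit link;
    ``log(1 + 1/lambda)`` for the Poisson-log link via the lognormal
    approximation).  Conditional adds the random-intercept variance to the
    numerator.
    """
    X = fit._design["X"]
    beta = fit.coef["estimate"].to_numpy()
    var_f = float(np.var(X @ beta))
    var_r = float(sum(v**2 for v in fit.re_sd.values()))
    if fit.spec.family == "binomial":
        var_d = np.pi**2 / 3.0
    else:
        lam = np.exp(np.mean(X @ beta) + 0.5 * var_r)
        var_d = float(np.log(1.0 + 1.0 / lam))
    denom = var_f + var_r + var_d
    return var_f / denom, (var_f + var_r) / denom


def simulate_response(
    fit: MixedModelFit, rng: np.random.Generator, n_sim: int = 1
) -> np.ndarray:
    """Simulate ``n_sim`` response vectors from the fitted model.

    Random intercepts are redrawn from their fitted distribution on each
    simulation (unconditional simulation), as residual diagnostics expect.
    """
    X = fit._design["X"]
    Zs = fit._design["Zs"]
    beta = fit.coef["estimate"].to_numpy()
    eta_fixed = X @ beta
    out = np.empty((n_sim, len(eta_fixed)))
    for s in range(n_sim):
        eta = eta_fixed.copy()
        for Z, (gname, sd) in zip(Zs, fit.re_sd.items()):
            eta += Z @ rng.normal(0.0, sd, Z.shape[1])
        if fit.spec.family == "binomial":
            out[s] = rng.random(len(eta)) < expit(eta)
        else:
            out[s] = rng.poisson(np.exp(np.clip(eta, -30, 30)))
    return out


def quantile_residuals(
    fit: MixedModelFit, n_sim: int = 250, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Simulation-based randomized quantile residuals plus KS uniformity p.

    Each observation is ranked within ``n_sim`` simulated responses with
    uniform tie-breaking; under a correctly specified model the residuals
    are Uniform(0, 1).
    """
    import warnings

    if n_sim < 50:
        warnings.warn("n_sim < 50 gives coarse quantile residuals", stacklevel=2)
    rng = np.random.default_rng(seed)
    sims = simulate_response(fit, rng, n_sim)
    y = fit._design["y"]
    below = (sims < y).sum(axis=0)
    ties = (sims == y).sum(axis=0)
    u = (below + rng.random(len(y)) * (ties + 1)) / (n_sim + 1)
    if np.std(sims) == 0:
        raise ValueError("degenerate (constant) simulated response")
    ks = stats.kstest(u, "uniform")
    return u, float(ks.pvalue)
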