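"""Latent-Gaussian spatial (and phylospatial) GLMMs via Laplace approximation.

The corrective model of the workflow: y_i ~ family(g^-1(x_i' beta + u_i))
with a latent field u ~ MVN(0, Sigma(theta)), Sigma = sigma2_s K_s(rho)
[+ sigma2_p K_p] + tau2 I, where K_s is a unit-diagonal distance-decay
kernel and K_p a unit-diagonal phylogenetic correlation.  If the data carry
no autocorrelation the variance components collapse towards zero and the
model degrades continuously to the ordinary GLM — the question "does the
covariate retain predictive power once proximity (and relatedness) is taken
into account" is answered by the fixed-effect inference in this model.

Fitting: for the binomial family the marginal likelihood is approximated by
a Laplace expansion around the joint penalized mode of (beta, u), found by
penalized iteratively reweighted least squares (PIRLS); the variance
parameters are optimized on the log scale in an outer quasi-Newton loop
with a Nelder-Mead fallback.  For the Gaussian family the marginal
likelihood is available in closed form (generalized least squares), which
the Laplace expansion reproduces exactly; the closed form is used and
cross-checked.  Wald covariance for beta is (X' (W^-1 + Sigma)^-1 X)^-1,
the Laplace-approximate information with the latent field integrated out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .covariance import CovarianceMatrix, KernelSpec, kernel_correlation, phylo_covariance
from .geo import DistanceMatrix, GeoTable, ValidationError, distance_matrix
from .glm import ModelFit, design_matrix, fit_glm, parse_formula

__all__ = ["SpatialModelFit", "fit_spatial_glmm", "compare_models", "OptimizerError"]

_PARAM_ORDER = ("sigma2_s", "rho", "tau2", "sigma2_p")
_LOG_BOUNDS = {
    "sigma2_s": (np.log(1e-8), np.log(50.0)),
    "rho": (np.log(1.0), np.log(20015.0)),
    "tau2": (np.log(1e-8), np.log(50.0)),
    "sigma2_p": (np.log(1e-8), np.log(50.0)),
}
#: identifiability floor for the nugget, on the latent variance scale
TAU2_FLOOR = 1e-6


class OptimizerError(RuntimeError):
    pass


class InternalConsistencyError(RuntimeError):
    pass


@dataclass
class SpatialModelFit(ModelFit):
    """GLM fit fields plus variance components and the latent-field mode.

    ``loglik`` is the Laplace-approximate marginal log-likelihood (exact
    for the Gaussian family); AIC counts the fixed effects plus every free
    variance parameter.  ``u`` is the conditional mode of the random
    effect; ``comparison`` is filled by :func:`compare_models`.
    """

    variance_components: dict = field(default_factory=dict)
    free_params: list[str] = field(default_factory=list)
    u: np.ndarray | None = None
    optimizer: dict = field(default_factory=dict)
    comparison: dict | None = None

    @property
    def k_params(self) -> int:  # fixed effects + free variance parameters
        return self.k_coef + len(self.free_params)

    def to_dict(self) -> dict:
        out = super().to_dict()
        out["variance_components"] = {k: float(v) for k, v in self.variance_components.items()}
        out["free_params"] = list(self.free_params)
        out["optimizer"] = self.optimizer
        if self.comparison is not None:
            out["comparison"] = self.comparison
        return out


def _chol_with_inflation(sigma: np.ndarray, max_tries: int = 6):
    """Cholesky with escalating diagonal inflation; None if hopeless."""
    jitter = 0.0
    scale = float(np.mean(np.diag(sigma))) or 1.0
    for t in range(max_tries):
        try:
            return linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]), lower=True), jitter
        except linalg.LinAlgError:
            jitter = scale * 10.0 ** (-10 + 2 * t)
    return None, jitter


def _pirls(X, y, sigma_inv, beta, u, max_iter=60, tol=1e-9):
    """Joint Newton for the penalized Bernoulli objective over (beta, u).

    psi(beta, u) = sum_i [y_i eta_i - log(1+e^eta_i)] - u' Sigma^-1 u / 2.
    Returns the joint mode, the IRLS weights there, and psi at the mode.
    """
    n, k = X.shape[0], X.shape[1]

    def psi(beta, u):
        eta = X @ beta + u
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * u @ sigma_inv @ u)

    cur = psi(beta, u)
    for _ in range(max_iter):
        eta = X @ beta + u
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        gb = X.T @ (y - mu)
        gu = (y - mu) - sigma_inv @ u
        gnorm = max(np.max(np.abs(gb)), np.max(np.abs(gu)))
        if gnorm < tol:
            break
        Xw = X * w[:, None]
        H = np.empty((k + n, k + n))
        H[:k, :k] = X.T @ Xw
        H[:k, k:] = Xw.T
        H[k:, :k] = Xw
        H[k:, k:] = sigma_inv
        H[k:, k:][np.diag_indices(n)] += w
        try:
            step = linalg.solve(H, np.concatenate([gb, gu]), assume_a="pos")
        except linalg.LinAlgError:
            step = np.linalg.lstsq(H, np.concatenate([gb, gu]), rcond=None)[0]
        t = 1.0
        for _ls in range(30):
            nb, nu = beta + t * step[:k], u + t * step[k:]
            new = psi(nb, nu)
            if new > cur - 1e-12:
                break
            t *= 0.5
        beta, u, cur = nb, nu, new
    eta = X @ beta + u
    mu = 1.0 / (1.0 + np.exp(-eta))
    return beta, u, mu * (1.0 - mu), cur, mu


def _unpack(theta_log, free, fixed):
    params = dict(fixed)
    for name, v in zip(free, theta_log):
        params[name] = float(np.exp(v))
    return params


def fit_spatial_glmm(
    table: GeoTable,
    formula: str,
    family: str = "binomial",
    kernel: KernelSpec | None = None,
    phylo=None,
    fix: dict | None = None,
    standardize: bool = False,
    rho_grid=None,
    maxiter: int = 200,
    seed: int | None = None,
    reml: bool = True,
) -> SpatialModelFit:
    """Fit the latent-Gaussian spatial GLMM by Laplace-approximate ML.

    Parameters
    ----------
    kernel:
        Kernel family/smoothness plus *starting values* for sigma2_s, rho
        and tau2 (all three estimated unless pinned via ``fix``).
    phylo:
        Optional tree (Newick/dendropy) or classification table; adds a
        unit-diagonal phylogenetic correlation with its own free variance
        sigma2_p.
    fix:
        Mapping of parameter name (sigma2_s, rho, tau2, sigma2_p) to a
        fixed value, excluded from optimization.  Fixing every variance
        component to zero reproduces the ordinary GLM exactly.
    rho_grid:
        Optional iterable of rho values: profile over this fixed grid
        instead of optimizing rho (fallback for flat likelihoods).
    """
    if table.n < 10:
        raise ValidationError("spatial GLMM requires at least 10 observations")
    kernel = kernel or KernelSpec()
    fix = dict(fix or {})
    outcome, covariates = parse_formula(formula)
    work = GeoTable(
        table.data,
        id_col=table.id_col,
        lon_col=table.lon_col,
        lat_col=table.lat_col,
        outcome_col=outcome,
        covariate_cols=covariates,
    )
    X, names = design_matrix(work, covariates, standardize=standardize)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError("design matrix is rank deficient")
    y = work.require_binary_outcome() if family == "binomial" else work.outcome
    if family not in ("binomial", "gaussian"):
        raise ValidationError(f"unsupported family '{family}'")

    D = distance_matrix(work)
    K_p = None
    if phylo is not None:
        K_p = phylo_covariance(phylo, work.ids).correlation_scaled()
    elif "sigma2_p" not in fix:
        fix["sigma2_p"] = 0.0

    tau2_floor = TAU2_FLOOR * (float(np.var(y)) if family == "gaussian" else 1.0)
    free = [p for p in _PARAM_ORDER if p not in fix]
    if fix.get("sigma2_s", None) == 0.0 and "rho" in free:
        free.remove("rho")  # rho unidentifiable without a spatial field
        fix["rho"] = kernel.rho

    # ---- degenerate limit: no random effect at all -> exact GLM
    if all(fix.get(p, None) == 0.0 for p in ("sigma2_s", "tau2", "sigma2_p")):
        g = fit_glm(work, formula, family=family, standardize=standardize)
        return SpatialModelFit(
            names=g.names, beta=g.beta, se=g.se, family=g.family, loglik=g.loglik,
            n=g.n, fitted=g.fitted, pearson_resid=g.pearson_resid,
            deviance_resid=g.deviance_resid, n_iter=g.n_iter, grad_norm=g.grad_norm,
            converged=True, ids=g.ids, scale=g.scale,
            variance_components={"sigma2_s": 0.0, "rho": fix["rho"], "tau2": 0.0, "sigma2_p": 0.0},
            free_params=[], u=np.zeros(g.n),
            optimizer={"method": "degenerate-glm", "evaluations": 0},
        )

    start = {
        "sigma2_s": max(kernel.sigma2, 1e-4),
        "rho": kernel.rho,
        "tau2": max(kernel.tau2, 10.0 * tau2_floor, 1e-3),
        "sigma2_p": 0.1,
    }

    def build_sigma(params):
        sigma = params["tau2"] * np.eye(n)
        if params["sigma2_s"] > 0:
            sigma = sigma + params["sigma2_s"] * kernel_correlation(
                D.values, kernel.family, kernel.nu, params["rho"]
            )
        if K_p is not None and params["sigma2_p"] > 0:
            sigma = sigma + params["sigma2_p"] * K_p
        return sigma

    state = {"beta": np.zeros(k), "u": np.zeros(n), "evals": 0}
    if family == "binomial":
        # crude start for the intercept keeps early PIRLS steps small
        pbar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        state["beta"][0] = np.log(pbar / (1 - pbar))

    def laplace_at(params):
        """(negative objective, mode cache) at clamped params.

        The cache's ``ll`` is always the (Laplace) *ML* marginal
        log-likelihood; with ``reml`` the returned objective additionally
        integrates the fixed effects out (penalty 1/2 log det of the
        beta information), which is what the variance parameters are
        optimized against.
        """
        params = dict(params)
        params["tau2"] = max(params["tau2"], tau2_floor)
        sigma = build_sigma(params)
        L, _ = _chol_with_inflation(sigma)
        if L is None:
            return np.inf, None
        state["evals"] += 1
        if family == "gaussian":
            # exact marginal: y ~ N(X beta, Sigma)
            rhs = linalg.cho_solve((L, True), np.column_stack([X, y]))
            Vi_X, Vi_y = rhs[:, :k], rhs[:, k]
            xtvx = X.T @ Vi_X
            beta = linalg.solve(xtvx, X.T @ Vi_y, assume_a="pos")
            r = y - X @ beta
            Vi_r = linalg.cho_solve((L, True), r)
            if np.max(np.abs(X.T @ Vi_r)) > 1e-6 * max(1.0, np.max(np.abs(X.T @ Vi_y))):
                raise InternalConsistencyError("GLS normal equations violated")
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
            ll = -0.5 * (n * np.log(2 * np.pi) + logdet + float(r @ Vi_r))
            cache = {"beta": beta, "r": r, "L": L, "sigma": sigma, "params": params, "ll": ll}
            objective = ll - (0.5 * np.linalg.slogdet(xtvx)[1] if reml else 0.0)
            return -objective, cache
        sigma_inv = linalg.cho_solve((L, True), np.eye(n))
        beta, u, w, psi, mu = _pirls(X, y, sigma_inv, state["beta"].copy(), state["u"].copy())
        state["beta"], state["u"] = beta, u  # warm start for the next step
        # log det(I + Sigma W) = log det Sigma + log det(Sigma^-1 + W)
        A = sigma_inv + np.diag(w)
        La, _ = _chol_with_inflation(A)
        if La is None:
            return np.inf, None
        logdet = 2.0 * float(np.log(np.diag(L)).sum()) + 2.0 * float(np.log(np.diag(La)).sum())
        ll = psi - 0.5 * logdet
        cache = {
            "beta": beta, "u": u, "w": w, "mu": mu, "sigma": sigma,
            "sigma_inv": sigma_inv, "params": params, "ll": ll,
        }
        objective = ll
        if reml:
            # beta information via Woodbury: X'WX - (WX)' (Sigma^-1 + W)^-1 (WX)
            Xw = X * w[:, None]
            info_beta = X.T @ Xw - Xw.T @ linalg.cho_solve((La, True), Xw)
            sign, ld = np.linalg.slogdet(info_beta)
            if sign <= 0:
                return np.inf, None
            objective = ll - 0.5 * ld
        return -objective, cache

    # fixed params fall back to their starting values (e.g. rho when the
    # spatial variance is pinned at zero)
    fixed_full = {**{p: start[p] for p in _PARAM_ORDER}, **fix}

    def objective(theta_log):
        return laplace_at(_unpack(theta_log, free, fixed_full))[0]

    trace = []
    if free:
        if rho_grid is not None and "rho" in free:
            sub_free = [p for p in free if p != "rho"]
            best = (np.inf, None, None)
            for r_val in rho_grid:
                fixed_r = dict(fixed_full, rho=float(r_val))

                def obj_r(tl, fr=fixed_r):
                    return laplace_at(_unpack(tl, sub_free, fr))[0]

                x0 = np.array([np.log(start[p]) for p in sub_free])
                res = optimize.minimize(
                    obj_r, x0, method="L-BFGS-B",
                    bounds=[_LOG_BOUNDS[p] for p in sub_free],
                    options={"maxiter": maxiter, "eps": 1e-5, "gtol": 1e-5},
                )
                trace.append({"rho": float(r_val), "fun": float(res.fun)})
                if res.fun < best[0]:
                    best = (res.fun, res.x, fixed_r)
            if best[1] is None:
                raise OptimizerError(f"profile over rho grid failed; trace: {trace}")
            params_hat = _unpack(best[1], sub_free, best[2])
            opt_meta = {"method": "profile-rho-grid", "trace": trace}
        else:
            x0 = np.array([np.log(start[p]) for p in free])
            bounds = [_LOG_BOUNDS[p] for p in free]
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "eps": 1e-5, "gtol": 1e-5, "ftol": 1e-11},
            )
            trace.append({"method": "L-BFGS-B", "fun": float(res.fun), "success": bool(res.success),
                          "message": str(res.message), "nit": int(res.nit)})
            best_x, best_f = (res.x, res.fun) if np.isfinite(res.fun) else (x0, np.inf)
            if not res.success or not np.isfinite(res.fun):
                res2 = optimize.minimize(
                    objective, best_x, method="Nelder-Mead",
                    options={"maxiter": 40 * maxiter, "xatol": 1e-4, "fatol": 1e-7},
                )
                trace.append({"method": "Nelder-Mead", "fun": float(res2.fun),
                              "success": bool(res2.success)})
                if np.isfinite(res2.fun) and res2.fun <= best_f:
                    best_x, best_f = res2.x, res2.fun
            if not np.isfinite(best_f):
                raise OptimizerError(f"spatial GLMM optimizer failed; trace: {trace}")
            # clip back into bounds (Nelder-Mead is unconstrained)
            best_x = np.clip(best_x, [b[0] for b in bounds], [b[1] for b in bounds])
            params_hat = _unpack(best_x, free, fixed_full)
            opt_meta = {"method": "L-BFGS-B+fallback", "trace": trace}
    else:
        params_hat = dict(fixed_full)
        opt_meta = {"method": "fixed", "trace": []}

    neg_ll, cache = laplace_at(params_hat)
    if cache is None:
        raise OptimizerError(f"covariance not PSD at the optimum; params {params_hat}")
    params_hat = cache["params"]
    ll = cache["ll"]
    beta = cache["beta"]
    sigma = cache["sigma"]
    opt_meta["evaluations"] = state["evals"]

    if family == "gaussian":
        L = cache["L"]
        Vi_X = linalg.cho_solve((L, True), X)
        cov_beta = linalg.inv(X.T @ Vi_X)
        se = np.sqrt(np.diag(cov_beta))
        r = cache["r"]
        tau2_hat = max(params_hat["tau2"], tau2_floor)
        Vi_r = linalg.cho_solve((L, True), r)
        u_hat = (sigma - tau2_hat * np.eye(n)) @ Vi_r
        fitted = X @ beta + u_hat
        resid = y - fitted
        sd = np.sqrt(tau2_hat)
        pearson = resid / sd
        devres = pearson
        mu = fitted
    else:
        u_hat = cache["u"]
        w = cache["w"]
        mu = cache["mu"]
        # Laplace-approximate marginal information for beta
        M = sigma + np.diag(1.0 / np.maximum(w, 1e-10))
        Lm, _ = _chol_with_inflation(M)
        Mi_X = linalg.cho_solve((Lm, True), X)
        cov_beta = linalg.inv(X.T @ Mi_X)
        se = np.sqrt(np.diag(cov_beta))
        fitted = mu
        pearson = (y - mu) / np.sqrt(np.maximum(w, 1e-12))
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_i = -2.0 * (
                y * np.log(np.where(y == 1, mu, 1)) + (1 - y) * np.log(np.where(y == 0, 1 - mu, 1))
            )
        devres = np.sign(y - mu) * np.sqrt(np.clip(dev_i, 0.0, None))

    return SpatialModelFit(
        names=names, beta=np.asarray(beta, float), se=se, family=family, loglik=float(ll),
        n=n, fitted=fitted, pearson_resid=pearson, deviance_resid=devres,
        n_iter=state["evals"], grad_norm=float("nan"), converged=True, ids=work.ids,
        scale=(params_hat["tau2"] if family == "gaussian" else None),
        variance_components={p: float(params_hat[p]) for p in _PARAM_ORDER},
        free_params=list(free), u=np.asarray(u_hat, float), optimizer=opt_meta,
    )


def compare_models(
    naive: ModelFit,
    spatial: SpatialModelFit,
    focal: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Naive-vs-spatial verdict on the focal covariate.

    Verdicts: "spatially_robust" (significant at alpha in both),
    "explained_by_space" (naive only), "space_revealed" (spatial only),
    "no_association" (neither).  Also reports Delta beta and
    Delta AIC = AIC_naive - AIC_spatial (positive favours the spatial model).
    The result is stored on ``spatial.comparison`` and returned.
    """
    if naive.n != spatial.n:
        raise ValidationError("model comparison requires fits to the same rows")
    if naive.names != spatial.names:
        raise ValidationError("model comparison requires the same formula")
    if focal is None:
        non_int = [nm for nm in naive.names if nm != "(Intercept)"]
        if not non_int:
            raise ValidationError("no focal covariate available (intercept-only model)")
        focal = non_int[0]
    i, j = naive.coef_index(focal), spatial.coef_index(focal)
    p_naive, p_spatial = float(naive.p[i]), float(spatial.p[j])
    sig_n, sig_s = p_naive < alpha, p_spatial < alpha
    verdict = {
        (True, True): "spatially_robust",
        (True, False): "explained_by_space",
        (False, False): "no_association",
        (False, True): "space_revealed",
    }[(sig_n, sig_s)]
    record = {
        "focal": focal,
        "alpha": alpha,
        "p_naive": p_naive,
        "p_spatial": p_spatial,
        "beta_naive": float(naive.beta[i]),
        "beta_spatial": float(spatial.beta[j]),
        "delta_beta": float(spatial.beta[j] - naive.beta[i]),
        "aic_naive": float(naive.aic),
        "aic_spatial": float(spatial.aic),
        "delta_aic": float(naive.aic - spatial.aic),
        "verdict": verdict,
    }
    spatial.comparison = record
    return record
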