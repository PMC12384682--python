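"""Binomial generalized linear mixed models with a patient random intercept.

Model: y_ij ~ Bernoulli(expit(x_ij'β + b_i)), b_i ~ N(0, σ_b²) i.i.d. per
patient.  The marginal likelihood integrates the random intercept out of
each patient's contribution:

    L_i(β, σ_b) = ∫ φ(b; 0, σ_b) Π_j expit(η_ij + b)^y (1−expit)^{1−y} db

evaluated by adaptive Gauss–Hermite quadrature: nodes are recentred at each
group's posterior mode and rescaled by the curvature there (default 25
nodes), which keeps the rule accurate even when a group's posterior is far
from, or much narrower than, the prior.  Optimization is deterministic
quasi-Newton (L-BFGS-B) on (β, log σ_b); the gradient is the exact marginal
score obtained from the same quadrature pass via Fisher's identity
(posterior-expected complete-data score), so no stochastic or
finite-difference machinery enters the likelihood climb.  Inference on the
fixed effects is Wald (matching the default summary of the R lme4 workflow
this mirrors); nested fits are compared with chi-square likelihood-ratio
(ANOVA) tests.  No multiplicity correction is applied anywhere — the
analysis this package supports is explicitly exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2, norm

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_LS_BOUNDS = (-8.0, 3.0)      # log σ_b; the lower bound is numerically σ_b=0


class SeparationError(RuntimeError):
    """Raised when the outcome has a single class (no fit possible)."""


# ---------------------------------------------------------------------------
# design matrices

TIME_GROUP_LEVELS = (1, 2, 3, 4)
ROOM_GROUP_REF = "living room"


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one model (intercept always included).

    ``terms`` may contain the categoricals ``time_group`` (reference group
    1, [8,12)) and ``maj_room_group`` (reference "living room"), numeric
    feature columns such as ``z_sound_sd``, and ``a:b`` interactions whose
    main effects must both be present.
    """

    outcome: str
    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":", 1)
                if a not in self.terms or b not in self.terms:
                    raise ValueError(
                        f"interaction {t!r} requires both main effects")

    @property
    def columns(self) -> list[str]:
        """Data columns the spec needs (outcome + flattened terms)."""
        cols = {self.outcome}
        for t in self.terms:
            cols.update(t.split(":"))
        return sorted(cols)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (self.outcome == other.outcome
                and set(self.terms) <= set(other.terms))


def _dummies(values: np.ndarray, levels: list, ref, prefix: str):
    cols, names = [], []
    for lev in levels:
        if lev == ref:
            continue
        cols.append((values == lev).astype(np.float64))
        names.append(f"{prefix}[{lev}]")
    return cols, names


def build_design(df: pd.DataFrame, spec: ModelSpec):
    """(y, X, term names, group codes) from a feature table.

    Categorical encodings use only levels present in the data (an absent
    time group contributes no column rather than a singular one).
    """
    y = df[spec.outcome].to_numpy(dtype=np.float64)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    pieces: dict[str, tuple[list[np.ndarray], list[str]]] = {}
    for t in spec.terms:
        if ":" in t:
            continue
        if t == "time_group":
            v = df[t].to_numpy()
            levels = [g for g in TIME_GROUP_LEVELS if (v == g).any()]
            pieces[t] = _dummies(v, levels, levels[0], t)
        elif t == "maj_room_group":
            v = df[t].to_numpy()
            levels = sorted(set(v))
            ref = ROOM_GROUP_REF if ROOM_GROUP_REF in levels else levels[0]
            pieces[t] = _dummies(v, levels, ref, t)
        else:
            pieces[t] = ([df[t].to_numpy(dtype=np.float64)], [t])
        c, n = pieces[t]
        cols.extend(c)
        names.extend(n)
    for t in spec.terms:
        if ":" not in t:
            continue
        a, b = t.split(":", 1)
        for ca, na in zip(*pieces[a]):
            for cb, nb in zip(*pieces[b]):
                cols.append(ca * cb)
                names.append(f"{na}:{nb}")
    X = np.column_stack(cols)
    groups = pd.factorize(df["patient_id"].to_numpy())[0]
    return y, X, names, groups


# ---------------------------------------------------------------------------
# core fit


@dataclass
class GlmmFit:
    spec: ModelSpec | None
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma_b: float
    loglik: float
    n_obs: int
    n_groups: int
    n_quad: int
    converged: bool
    message: str = ""
    row_index: np.ndarray | None = None     # rows of the source table used

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def df_fixed(self) -> int:
        return len(self.terms)

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.wald_z))

    @property
    def conf_int(self) -> np.ndarray:
        half = 1.96 * self.se
        return np.column_stack([self.beta - half, self.beta + half])

    def __getitem__(self, term: str) -> dict[str, float]:
        if term not in self.terms:
            raise KeyError(term)
        i = self.terms.index(term)
        lo, hi = self.conf_int[i]
        return {"beta": float(self.beta[i]), "se": float(self.se[i]),
                "z": float(self.wald_z[i]), "p": float(self.pvalues[i]),
                "ci": (float(lo), float(hi))}

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame({
            "term": self.terms, "beta": self.beta, "se": self.se,
            "z": self.wald_z, "p": self.pvalues,
            "ci_lo": ci[:, 0], "ci_hi": ci[:, 1],
        })


class _MarginalLoglik:
    """Adaptive Gauss–Hermite marginal log-likelihood and exact score."""

    def __init__(self, y, X, groups, n_quad=25):
        order = np.argsort(groups, kind="stable")
        self.y = np.asarray(y, dtype=np.float64)[order]
        self.X = np.asarray(X, dtype=np.float64)[order]
        g = np.asarray(groups)[order]
        change = np.flatnonzero(np.diff(g)) + 1
        self.idx = np.concatenate(([0], change))          # group starts
        self.G = len(self.idx)
        self.gidx = np.repeat(np.arange(self.G),
                              np.diff(np.concatenate((self.idx, [len(g)]))))
        # probabilists' Hermite rule: ∫ g(u) exp(-u²/2) du = Σ w_k g(z_k)
        z, w = hermegauss(n_quad)
        self.z_k = z
        self.logw = np.log(w)
        self.n_quad = n_quad
        self._b_mode = np.zeros(self.G)                   # warm start

    def _modes(self, eta0, inv_s2):
        """Posterior mode and curvature of b per group (Newton)."""
        b = self._b_mode.copy()
        for _ in range(60):
            eta = eta0 + b[self.gidx]
            p = expit(eta)
            score = np.add.reduceat(self.y - p, self.idx) - b * inv_s2
            w = np.add.reduceat(p * (1.0 - p), self.idx) + inv_s2
            step = np.clip(score / w, -4.0, 4.0)
            b += step
            if np.max(np.abs(step)) < 1e-11:
                break
        eta = eta0 + b[self.gidx]
        p = expit(eta)
        h = np.add.reduceat(p * (1.0 - p), self.idx) + inv_s2
        self._b_mode = b
        return b, h

    def __call__(self, theta):
        """Negative loglik and gradient at theta = (β, log σ_b)."""
        beta, ls = theta[:-1], theta[-1]
        sigma = np.exp(ls)
        inv_s2 = 1.0 / (sigma * sigma)
        eta0 = self.X @ beta
        b_hat, h = self._modes(eta0, inv_s2)
        s = 1.0 / np.sqrt(h)                              # adaptive scale

        q = self.n_quad
        term = np.empty((self.G, q))
        resid = np.empty((q, len(self.y)))
        b_nodes = np.empty((q, self.G))
        for k in range(q):
            b_k = b_hat + s * self.z_k[k]
            eta = eta0 + b_k[self.gidx]
            p = expit(eta)
            ll_obs = self.y * eta - np.logaddexp(0.0, eta)
            term[:, k] = (self.logw[k] + 0.5 * self.z_k[k] ** 2
                          + np.add.reduceat(ll_obs, self.idx)
                          - 0.5 * b_k * b_k * inv_s2 - ls - _LOG_SQRT_2PI
                          + np.log(s))
            resid[k] = self.y - p
            b_nodes[k] = b_k
        m = term.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(term - m).sum(axis=1))
        loglik = float(lse.sum())
        c = np.exp(term - lse[:, None])                   # posterior weights

        r = np.zeros(len(self.y))
        for k in range(q):
            r += c[:, k][self.gidx] * resid[k]
        grad_beta = self.X.T @ r
        grad_ls = float(((b_nodes.T ** 2 * c).sum(axis=1) * inv_s2 - 1.0).sum())
        return -loglik, -np.concatenate([grad_beta, [grad_ls]])

    def loglik_only(self, theta) -> float:
        return -self(theta)[0]


def _logistic_start(y, X, ridge=1e-6, n_iter=30):
    """Plain logistic Newton fit used as a deterministic starting point."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        p = expit(X @ beta)
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
        g = X.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def fit_glmm(
    y, X, groups, term_names: list[str] | None = None,
    spec: ModelSpec | None = None, n_quad: int = 25,
    fix_sigma: float | None = None, start: np.ndarray | None = None,
    row_index=None,
) -> GlmmFit:
    """Maximum (marginal) likelihood fit; deterministic given the data.

    ``fix_sigma`` pins the random-intercept SD (``0`` reduces the model to
    plain logistic regression); otherwise (β, log σ_b) are profiled jointly.
    A fit flagged non-converged (including quasi-separation, |β̂| > 15) is
    still returned with diagnostics rather than raised.
    """
    y = np.asarray(y, dtype=np.float64)
    uy = np.unique(y)
    if not np.isin(uy, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if len(uy) < 2:
        raise SeparationError("outcome has a single class")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    p = X.shape[1]
    names = term_names or [f"x{i}" for i in range(p)]
    f = _MarginalLoglik(y, X, groups, n_quad=n_quad)
    beta0 = start[:p] if start is not None else _logistic_start(y, X)

    if fix_sigma is not None:
        ls_fix = max(np.log(fix_sigma), _LS_BOUNDS[0]) if fix_sigma > 0 \
            else _LS_BOUNDS[0]

        def f_beta(beta):
            nll, g = f(np.concatenate([beta, [ls_fix]]))
            return nll, g[:p]

        res = minimize(f_beta, beta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "gtol": 1e-8, "ftol": 1e-14})
        theta = np.concatenate([res.x, [ls_fix]])
        free = p
    else:
        ls0 = start[-1] if start is not None and len(start) == p + 1 else 0.0
        bounds = [(None, None)] * p + [_LS_BOUNDS]
        res = minimize(f, np.concatenate([beta0, [ls0]]), jac=True,
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "gtol": 1e-8, "ftol": 1e-14})
        theta = res.x
        free = p + 1

    loglik = -f(theta)[0]
    # observed information by central differences of the analytic score
    H = np.zeros((free, free))
    for j in range(free):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = f(tp)[1] if fix_sigma is None else f(tp)[1]
        gm = f(tm)[1]
        H[j] = (gp[:free] - gm[:free]) / (2.0 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
        spd = True
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        spd = False

    sigma_b = 0.0 if fix_sigma == 0 else float(np.exp(theta[-1]))
    if sigma_b < 1e-3:
        sigma_b = 0.0 if abs(theta[-1] - _LS_BOUNDS[0]) < 1e-6 else sigma_b
    separated = bool(np.any(np.abs(theta[:p]) > 15.0))
    converged = bool(res.success) and spd and not separated
    msg = res.message if isinstance(res.message, str) else str(res.message)
    if separated:
        msg = "possible complete separation: |beta| > 15; " + msg
    return GlmmFit(
        spec=spec, terms=names, beta=theta[:p].copy(), se=se,
        sigma_b=sigma_b, loglik=float(loglik), n_obs=len(y),
        n_groups=len(np.unique(groups)), n_quad=n_quad, converged=converged,
        message=msg,
        row_index=None if row_index is None else np.asarray(row_index),
    )


def fit_model(
    df: pd.DataFrame, spec: ModelSpec, n_quad: int = 25,
    fix_sigma: float | None = None, require_passed: bool = True,
) -> GlmmFit:
    """Fit a :class:`ModelSpec` on a feature table.

    Rows failing quality (when present) and rows with any undefined
    covariate among the spec's columns are dropped listwise.
    """
    sub = df
    if require_passed and "passed" in df.columns:
        sub = sub[sub["passed"]]
    num_cols = [c for c in spec.columns if c != "time_group"
                and c != "maj_room_group"]
    sub = sub.dropna(subset=[c for c in num_cols if c in sub.columns])
    y, X, names, groups = build_design(sub, spec)
    return fit_glmm(y, X, groups, term_names=names, spec=spec, n_quad=n_quad,
                    fix_sigma=fix_sigma, row_index=sub.index.to_numpy())


# ---------------------------------------------------------------------------
# likelihood-ratio (ANOVA) comparison


@dataclass
class LrtResult:
    delta_deviance: float
    delta_df: int
    pvalue: float
    keep: bool
    alpha: float = 0.05


def lrt(nested: GlmmFit, full: GlmmFit, alpha: float = 0.05) -> LrtResult:
    """Chi-square likelihood-ratio test of nested against full.

    Both fits must use exactly the same rows; the fuller model's extra
    terms must be a superset.  ``keep`` is True when the added complexity
    significantly improves the fit at ``alpha``.
    """
    if nested.spec is not None and full.spec is not None:
        if not nested.spec.is_nested_in(full.spec):
            raise ValueError("specs are not nested")
    elif not set(nested.terms) <= set(full.terms):
        raise ValueError("term sets are not nested")
    if nested.row_index is not None and full.row_index is not None:
        if not np.array_equal(nested.row_index, full.row_index):
            raise ValueError("fits use different rows; refit on common rows")
    elif nested.n_obs != full.n_obs:
        raise ValueError("fits use different numbers of rows")

    dd = nested.deviance - full.deviance
    if dd < -1e-6:
        raise RuntimeError(
            f"full model fits worse than nested (Δdeviance={dd:.3g}); "
            "optimizer failure — refit with a warm start")
    dd = max(dd, 0.0)
    ddf = full.df_fixed - nested.df_fixed
    pvalue = float(chi2.sf(dd, ddf)) if ddf > 0 else 1.0
    return LrtResult(dd, ddf, pvalue, keep=bool(pvalue < alpha), alpha=alpha)


def odds_ratio(fit: GlmmFit, term: str) -> dict[str, float]:
    """exp(β̂) with its exponentiated 95% Wald CI for one term."""
    est = fit[term]
    lo, hi = est["ci"]
    return {"or": float(np.exp(est["beta"])),
            "ci": (float(np.exp(lo)), float(np.exp(hi)))}
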