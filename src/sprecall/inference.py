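"""Random-intercept logistic models of recall and BIC-based model selection.

Every model has the form

    logit P(Resp_ij = 1) = x_ij' gamma + u_0j,   u_0j ~ Normal(0, psi)

with a per-subject random intercept u_0j and fixed effects gamma over word
descriptors (SP, word frequency, presentation order, ...). The marginal
likelihood integrates the product of Bernoulli terms over u_0j per subject;
the integral is approximated by Gauss-Hermite quadrature. Models are ranked
by BIC, BIC differences convert to Bayes factors via
BF10 = exp((BIC_0 - BIC_1)/2), and a backward-pruning search removes one
predictor family at a time while doing so lowers BIC.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "Term",
    "Interaction",
    "ModelSpec",
    "FitResult",
    "ComparisonTable",
    "build_design",
    "marginal_loglik",
    "RandomInterceptLogit",
    "fit_random_intercept_logit",
    "bic",
    "bic_bayes_factor",
    "compare_models",
    "prune_backward",
]


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One fixed-effect column: a descriptor, a power, an optional log10."""

    descriptor: str
    degree: int = 1
    log10: bool = False

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    @property
    def label(self) -> str:
        base = f"log10{self.descriptor}" if self.log10 else self.descriptor
        return base if self.degree == 1 else f"{base}^{self.degree}"


@dataclass(frozen=True)
class Interaction:
    """Elementwise product of two (already transformed) descriptors."""

    left: Term
    right: Term

    @property
    def label(self) -> str:
        return f"{self.left.label}:{self.right.label}"


_RANDOM_RE = re.compile(r"^\(\s*1\s*\|\s*(\w+)\s*\)$")
_POWER_RE = re.compile(r"^\(?([\w()]+?)\)?\^(\d+)$")
_LOG_RE = re.compile(r"^log_?10_?\(?(\w+)\)?$")


def _parse_term(tok: str) -> Term:
    degree = 1
    m = _POWER_RE.match(tok)
    if m:
        tok, degree = m.group(1), int(m.group(2))
    m = _LOG_RE.match(tok)
    if m:
        return Term(descriptor=m.group(1), degree=degree, log10=True)
    if not re.fullmatch(r"\w+", tok):
        raise ValueError(f"cannot parse model term {tok!r}")
    return Term(descriptor=tok, degree=degree)


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effects structure plus the random-intercept grouping factor.

    Usually built from a formula in the field's notation, e.g.
    ``Resp ~ (1|Subj) + Order + Order^2 + SP``.
    """

    terms: tuple[Term, ...] = ()
    interactions: tuple[Interaction, ...] = ()
    group: str = "Subj"
    response: str = "Resp"
    label: str | None = None

    def __post_init__(self) -> None:
        seen = {t.label for t in self.terms}
        for t in self.terms:
            if t.degree > 1:
                linear = replace(t, degree=1)
                if linear.label not in seen:
                    raise ValueError(
                        f"quadratic term {t.label} requires its linear term"
                    )
        for ia in self.interactions:
            for side in (ia.left, ia.right):
                if side.label not in seen:
                    raise ValueError(
                        f"interaction {ia.label} references absent term {side.label}"
                    )
        if self.label is None:
            object.__setattr__(self, "label", self.formula())

    @classmethod
    def from_formula(cls, formula: str, label: str | None = None) -> "ModelSpec":
        rhs = formula.split("~", 1)[1] if "~" in formula else formula
        response = formula.split("~", 1)[0].strip() if "~" in formula else "Resp"
        group = "Subj"
        terms: list[Term] = []
        interactions: list[Interaction] = []
        for tok in (t.strip() for t in rhs.split("+")):
            if not tok or tok == "1":
                continue
            m = _RANDOM_RE.match(tok)
            if m:
                group = m.group(1)
                continue
            if ":" in tok:
                left, right = (s.strip() for s in tok.split(":", 1))
                interactions.append(Interaction(_parse_term(left), _parse_term(right)))
                continue
            terms.append(_parse_term(tok))
        return cls(
            terms=tuple(terms),
            interactions=tuple(interactions),
            group=group,
            response=response or "Resp",
            label=label,
        )

    def formula(self) -> str:
        parts = [f"(1|{self.group})"]
        parts += [t.label for t in self.terms]
        parts += [ia.label for ia in self.interactions]
        return f"{self.response} ~ " + " + ".join(parts)

    @property
    def descriptors(self) -> tuple[str, ...]:
        """Distinct descriptor names appearing in fixed terms, in order."""
        seen: list[str] = []
        for t in self.terms:
            if t.descriptor not in seen:
                seen.append(t.descriptor)
        return tuple(seen)

    def drop_descriptor(self, descriptor: str) -> "ModelSpec":
        """Spec with every term and interaction involving ``descriptor`` removed."""
        terms = tuple(t for t in self.terms if t.descriptor != descriptor)
        ias = tuple(
            ia
            for ia in self.interactions
            if descriptor not in (ia.left.descriptor, ia.right.descriptor)
        )
        return ModelSpec(
            terms=terms, interactions=ias, group=self.group, response=self.response
        )


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with leading intercept column) and column names."""

    def column(term: Term) -> np.ndarray:
        if term.descriptor not in df.columns:
            raise KeyError(f"model references absent descriptor {term.descriptor!r}")
        x = df[term.descriptor].to_numpy(dtype=float)
        if term.log10:
            x = np.log10(x)
        return x**term.degree

    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for t in spec.terms:
        cols.append(column(t))
        names.append(t.label)
    for ia in spec.interactions:
        cols.append(column(ia.left) * column(ia.right))
        names.append(ia.label)
    X = np.column_stack(cols)
    if np.any(~np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    return X, names


# --------------------------------------------------------------------------
# marginal likelihood
# --------------------------------------------------------------------------

def _subject_index(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes, len(uniques)


def marginal_loglik(
    gamma: np.ndarray,
    sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    groups,
    n_quad: int = 21,
) -> float:
    """Marginal log-likelihood of a random-intercept logit at fixed parameters.

    Per subject j, integrates prod_i Bernoulli(y_ij; expit(x_ij'gamma + u))
    over u ~ Normal(0, sigma^2) with ``n_quad``-node Gauss-Hermite
    quadrature (exact sum at u = 0 when sigma = 0).
    """
    gamma = np.asarray(gamma, dtype=float)
    y = np.asarray(y, dtype=float)
    idx, n_subj = _subject_index(groups)
    eta0 = X @ gamma
    if sigma == 0:
        return float(np.sum(y * eta0 - np.logaddexp(0.0, eta0)))
    nodes, weights = hermgauss(n_quad)
    u = np.sqrt(2.0) * sigma * nodes
    eta = eta0[:, None] + u[None, :]
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    per_subj = np.zeros((n_subj, n_quad))
    np.add.at(per_subj, idx, ll_obs)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    return float(logsumexp(per_subj + log_w[None, :], axis=1).sum())


def _marginal_nll_grad(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    n_subj: int,
    nodes: np.ndarray,
    log_w: np.ndarray,
    sigma_fixed: float | None = None,
) -> tuple[float, np.ndarray]:
    """Negative marginal log-likelihood and its analytic gradient.

    theta = (gamma, log sigma) when sigma is estimated, else theta = gamma.
    The gradient in gamma is the posterior-weighted score of the Bernoulli
    terms; the gradient in log sigma reuses the same node weights since
    u_k = sqrt(2) sigma z_k scales linearly with sigma.
    """
    p = X.shape[1]
    if sigma_fixed is None:
        gamma, sigma = theta[:p], float(np.exp(theta[p]))
    else:
        gamma, sigma = theta, sigma_fixed
    n_quad = nodes.size
    eta0 = X @ gamma
    u = np.sqrt(2.0) * sigma * nodes
    eta = eta0[:, None] + u[None, :]
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    per_subj = np.zeros((n_subj, n_quad))
    np.add.at(per_subj, idx, ll_obs)
    log_post = per_subj + log_w[None, :]
    log_lj = logsumexp(log_post, axis=1)
    ll = float(log_lj.sum())
    # posterior node weights per subject, broadcast back to observations
    a = np.exp(log_post - log_lj[:, None])  # (n_subj, n_quad)
    resid = y[:, None] - expit(eta)  # (n_obs, n_quad)
    w_obs = a[idx]  # (n_obs, n_quad)
    g_gamma = X.T @ np.sum(w_obs * resid, axis=1)
    if sigma_fixed is None:
        subj_resid = np.zeros((n_subj, n_quad))
        np.add.at(subj_resid, idx, resid)
        g_logsig = float(np.sum(a * subj_resid * u[None, :]))
        grad = np.append(g_gamma, g_logsig)
    else:
        grad = g_gamma
    return -ll, -grad


def _observed_information(grad_fn, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Hessian of the negative log-likelihood by central differences of the
    analytic gradient."""
    d = theta.size
    H = np.empty((d, d))
    for j in range(d):
        tp, tm = theta.copy(), theta.copy()
        h = step * max(1.0, abs(theta[j]))
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * h)
    return (H + H.T) / 2


def _fixed_only_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Plain logistic regression by L-BFGS with analytic gradient."""

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    def grad(beta):
        return X.T @ (expit(X @ beta) - y)

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-9})
    return res.x, -res.fun


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class RandomInterceptLogit(BaseEstimator, ClassifierMixin):
    """Logistic regression with a per-group Gaussian random intercept.

    Fits by maximising the Gauss-Hermite-approximated marginal likelihood
    over (gamma, log sigma), sigma^2 = psi. BIC uses k = number of fixed
    effects + 1 for psi (when psi is estimated) and n = number of trials.

    Parameters
    ----------
    n_quad : int
        Gauss-Hermite nodes (default 21; doubling it should not move the
        log-likelihood materially on well-behaved data).
    psi : float or None
        None estimates the random-intercept variance; a number fixes it
        (0 reduces the model to ordinary logistic regression).
    fit_intercept : bool
        Prepend an intercept column to X (ignored if X already carries one
        via :func:`build_design` — pass ``fit_intercept=False`` then).
    tol : float
        Convergence tolerance on the log-likelihood.

    Attributes
    ----------
    gamma_ : fixed-effect coefficients (intercept first when fitted).
    psi_ : random-intercept variance (0 with ``boundary_`` set when the
        estimate collapses onto the boundary).
    loglik_, bic_, k_, n_obs_, converged_, separation_ : fit diagnostics.
    """

    _SIGMA_FLOOR = 1e-4  # below this, psi is reported as exactly 0
    _START_SIGMA = 0.5

    def __init__(
        self,
        n_quad: int = 21,
        psi: float | None = None,
        fit_intercept: bool = True,
        tol: float = 1e-8,
        max_iter: int = 500,
    ):
        self.n_quad = n_quad
        self.psi = psi
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups=None) -> "RandomInterceptLogit":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("responses must be binary 0/1")
        y = y.astype(float)
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        estimate_psi = self.psi is None
        if estimate_psi or self.psi > 0:
            if groups is None:
                raise ValueError("groups are required unless psi=0")
            idx, n_subj = _subject_index(groups)
            if n_subj < 2 and estimate_psi:
                raise ValueError("need >= 2 groups to estimate psi")
        p = X.shape[1]

        gamma0, ll_glm = _fixed_only_fit(X, y)

        if not estimate_psi and self.psi == 0:
            self.gamma_ = gamma0
            self.psi_ = 0.0
            self.sigma_ = 0.0
            self.loglik_ = ll_glm
            self.k_ = p
            self.converged_ = True
            self.boundary_ = False
            w = expit(X @ gamma0) * (1 - expit(X @ gamma0))
            self.gamma_se_ = np.sqrt(np.diag(np.linalg.inv(X.T @ (X * w[:, None]))))
        else:
            nodes, weights = hermgauss(self.n_quad)
            log_w = np.log(weights) - 0.5 * np.log(np.pi)
            if estimate_psi:
                theta0 = np.append(gamma0, np.log(self._START_SIGMA))
                bounds = [(None, None)] * p + [(np.log(1e-6), np.log(50.0))]
                res = minimize(
                    _marginal_nll_grad, theta0, jac=True,
                    args=(X, y, idx, n_subj, nodes, log_w),
                    method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": self.max_iter,
                             "ftol": self.tol / 100, "gtol": 1e-7},
                )
                sigma = float(np.exp(res.x[p]))
                gamma = res.x[:p]
                self.k_ = p + 1
            else:
                sigma = float(np.sqrt(self.psi))
                res = minimize(
                    _marginal_nll_grad, gamma0, jac=True,
                    args=(X, y, idx, n_subj, nodes, log_w, sigma),
                    method="L-BFGS-B",
                    options={"maxiter": self.max_iter,
                             "ftol": self.tol / 100, "gtol": 1e-7},
                )
                gamma = res.x
                self.k_ = p
            self.converged_ = bool(res.success)
            self.boundary_ = estimate_psi and sigma < self._SIGMA_FLOOR
            if self.boundary_:
                sigma = 0.0
                gamma, ll = gamma0, ll_glm
            else:
                ll = -float(res.fun)
            self.gamma_ = gamma
            self.sigma_ = sigma
            self.psi_ = sigma**2
            self.loglik_ = ll
            if sigma > 0:
                if estimate_psi:
                    grad_fn = lambda t: _marginal_nll_grad(
                        t, X, y, idx, n_subj, nodes, log_w)[1]
                    theta_hat = np.append(gamma, np.log(sigma))
                else:
                    grad_fn = lambda t: _marginal_nll_grad(
                        t, X, y, idx, n_subj, nodes, log_w, sigma)[1]
                    theta_hat = gamma
                try:
                    cov = np.linalg.inv(_observed_information(grad_fn, theta_hat))
                    self.gamma_se_ = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
                except np.linalg.LinAlgError:
                    self.gamma_se_ = np.full(p, np.nan)
            else:
                w = expit(X @ gamma) * (1 - expit(X @ gamma))
                self.gamma_se_ = np.sqrt(
                    np.diag(np.linalg.inv(X.T @ (X * w[:, None])))
                )

        fitted_p = expit(X @ self.gamma_)
        perfectly_predicted = bool(
            np.all(fitted_p[y == 1] > 0.99) and np.all(fitted_p[y == 0] < 0.01)
        )
        self.separation_ = bool(np.any(np.abs(self.gamma_) > 25)) or perfectly_predicted
        if self.separation_:
            warnings.warn("possible complete separation: extreme coefficients",
                          stacklevel=2)
        self.n_obs_ = len(y)
        self.bic_ = -2.0 * self.loglik_ + self.k_ * np.log(self.n_obs_)
        if self.fit_intercept:
            self.intercept_ = self.gamma_[0]
            self.coef_ = self.gamma_[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = self.gamma_
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Population-averaged recall probabilities (random effect
        integrated out by quadrature)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        eta0 = X @ self.gamma_
        if self.sigma_ == 0:
            p1 = expit(eta0)
        else:
            nodes, weights = hermgauss(self.n_quad)
            u = np.sqrt(2.0) * self.sigma_ * nodes
            p1 = expit(eta0[:, None] + u[None, :]) @ (weights / np.sqrt(np.pi))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# --------------------------------------------------------------------------
# model-level wrappers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """A fitted random-intercept logistic model, keyed by its formula label."""

    label: str
    gamma: dict[str, float]
    psi: float
    loglik: float
    k: int
    n_obs: int
    bic: float
    converged: bool
    boundary: bool
    n_quad: int
    gamma_se: dict[str, float] = field(default_factory=dict)

    @property
    def gamma00(self) -> float:
        return self.gamma["(Intercept)"]


def fit_random_intercept_logit(
    df: pd.DataFrame,
    spec: ModelSpec,
    n_quad: int = 21,
    psi: float | None = None,
) -> FitResult:
    """Fit a :class:`ModelSpec` on a long-format trials frame."""
    if spec.response not in df.columns:
        raise KeyError(f"response column {spec.response!r} missing")
    if spec.group not in df.columns:
        raise KeyError(f"grouping column {spec.group!r} missing")
    X, names = build_design(df, spec)
    y = df[spec.response].to_numpy()
    est = RandomInterceptLogit(n_quad=n_quad, psi=psi, fit_intercept=False)
    est.fit(X, y, groups=df[spec.group].to_numpy())
    return FitResult(
        label=spec.label,
        gamma=dict(zip(names, est.gamma_)),
        gamma_se=dict(zip(names, est.gamma_se_)),
        psi=est.psi_,
        loglik=est.loglik_,
        k=est.k_,
        n_obs=est.n_obs_,
        bic=est.bic_,
        converged=est.converged_,
        boundary=est.boundary_,
        n_quad=n_quad,
    )


def bic(fit: FitResult) -> float:
    """BIC = -2 loglik + k ln(n_obs); lower is better."""
    return -2.0 * fit.loglik + fit.k * np.log(fit.n_obs) if fit.n_obs else 0.0


def bic_bayes_factor(bic_reference: float, bic_alternative: float) -> tuple[float, float]:
    """(BF10, posterior probability) of the alternative vs the reference.

    BF10 = exp((BIC_ref - BIC_alt)/2); posterior assumes equal model priors.
    """
    if not (np.isfinite(bic_reference) and np.isfinite(bic_alternative)):
        raise ValueError("BIC values must be finite")
    log_bf = (bic_reference - bic_alternative) / 2.0
    bf10 = float(np.exp(log_bf))
    posterior = float(np.exp(log_bf - logsumexp([0.0, log_bf])))
    return bf10, posterior


@dataclass(frozen=True)
class ComparisonTable:
    """Model zoo ranked by BIC, with BF10 / posterior vs a reference model."""

    table: pd.DataFrame
    reference: str
    fits: dict[str, FitResult] = field(repr=False, default_factory=dict)

    def to_json_dict(self) -> list[dict]:
        return self.table.replace({np.nan: None}).to_dict(orient="records")


def compare_models(
    df: pd.DataFrame,
    specs: list[ModelSpec],
    reference_label: str,
    n_quad: int = 21,
) -> ComparisonTable:
    """Fit every spec and tabulate BIC, delta BIC, BF10 and posterior.

    A spec that fails to fit is kept in the table with NaN statistics; the
    reference row carries BF10 = 1 and posterior = 0.5 by construction.
    """
    labels = [s.label for s in specs]
    if reference_label not in labels:
        raise ValueError(f"reference {reference_label!r} not among the specs")
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for s in specs:
        try:
            fits[s.label] = fit_random_intercept_logit(df, s, n_quad=n_quad)
        except Exception as exc:  # keep the table going
            errors[s.label] = str(exc)
    if reference_label not in fits:
        raise RuntimeError(
            f"reference model failed to fit: {errors[reference_label]}"
        )
    bic_ref = fits[reference_label].bic
    rows = []
    for s in specs:
        if s.label in fits:
            f = fits[s.label]
            bf10, post = bic_bayes_factor(bic_ref, f.bic)
            rows.append(dict(label=f.label, k=f.k, loglik=f.loglik, bic=f.bic,
                             delta_bic=f.bic - bic_ref, bf10=bf10,
                             posterior=post, converged=f.converged,
                             error=None))
        else:
            rows.append(dict(label=s.label, k=np.nan, loglik=np.nan,
                             bic=np.nan, delta_bic=np.nan, bf10=np.nan,
                             posterior=np.nan, converged=False,
                             error=errors[s.label]))
    table = pd.DataFrame(rows).sort_values(
        "bic", na_position="last", kind="stable"
    ).reset_index(drop=True)
    return ComparisonTable(table=table, reference=reference_label, fits=fits)


def prune_backward(
    df: pd.DataFrame,
    full_spec: ModelSpec,
    keep: tuple[str, ...] = (),
    n_quad: int = 21,
) -> tuple[ModelSpec, list[dict]]:
    """Backward model pruning: remove one predictor family at a time.

    A family is all fixed terms (and interactions) of one descriptor, so a
    linear+quadratic pair leaves together. Descriptors in ``keep`` (e.g. the
    order polynomial of the base model) are never removed. At each round the
    current model and every single-removal candidate are fitted; if the best
    candidate's BIC is lower (ties within 1e-9 resolved toward the smaller
    model), the search moves there; it stops when no removal helps.

    Returns the selected spec and an audit trail with every fitted candidate.
    """
    trail: list[dict] = []
    cache: dict[str, FitResult] = {}

    def fitted(spec: ModelSpec, step: int, action: str) -> FitResult:
        if spec.label not in cache:
            cache[spec.label] = fit_random_intercept_logit(df, spec, n_quad=n_quad)
        f = cache[spec.label]
        trail.append(dict(step=step, action=action, label=spec.label,
                          k=f.k, bic=f.bic, converged=f.converged))
        return f

    current = full_spec
    step = 0
    current_fit = fitted(current, step, "current")
    while True:
        removable = [d for d in current.descriptors if d not in keep]
        if not removable:
            break
        step += 1
        candidates = []
        for d in removable:
            cand = current.drop_descriptor(d)
            candidates.append((cand, fitted(cand, step, f"drop {d}")))
        best_spec, best_fit = min(
            candidates, key=lambda cf: (cf[1].bic, cf[1].k)
        )
        if best_fit.bic < current_fit.bic + 1e-9:
            current, current_fit = best_spec, best_fit
        else:
            break
    return current, trail
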