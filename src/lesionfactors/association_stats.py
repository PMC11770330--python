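"""Outcome statistics for lesion-disconnection cohorts.

Implements the full association toolkit: the any-domain impairment rule
(post-stroke cognitive impairment, PSCI, when any cognitive domain summary
z-score is at or below -1.5), cross-sectional logistic regression with
Wald odds ratios, nested-model likelihood-ratio tests, Benjamini-Hochberg
FDR control, first canonical correlation with a row-permutation null, a
longitudinal random-intercept logistic model integrated by adaptive
Gauss-Hermite quadrature, and 2x2 transition-table bookkeeping between the
two follow-up timepoints.

Plain logistic fits are delegated to statsmodels (IRLS/Newton maximum
likelihood); the mixed model is fit here because the marginal likelihood
over a scalar random intercept needs only one-dimensional quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logsumexp
from statsmodels.stats.multitest import multipletests
from statsmodels.tools import numdiff

__all__ = [
    "GLMFit",
    "CCAResult",
    "MixedFit",
    "TransitionTable",
    "PSCI_THRESHOLD",
    "domain_summary",
    "psci_classify",
    "fit_logistic",
    "lr_test",
    "bh_fdr",
    "cca_first",
    "fit_logistic_mixed",
    "transition_table",
]

#: Impairment threshold on domain summary z-scores (inclusive).
PSCI_THRESHOLD = -1.5


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)perfect separation."""


@dataclass
class GLMFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    ci95: np.ndarray  # (n_params, 2)
    p: np.ndarray
    loglik: float
    n_params: int
    n_obs: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "or": self.or_,
                "ci_low": self.ci95[:, 0],
                "ci_high": self.ci95[:, 1],
                "p": self.p,
            },
            index=self.names,
        )


@dataclass
class CCAResult:
    r1: float
    x_weights: np.ndarray
    y_weights: np.ndarray
    perm_p: float
    n_perm: int


@dataclass
class MixedFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    p: np.ndarray
    re_var: float
    loglik: float
    converged: bool
    n_subjects: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "or": self.or_, "p": self.p},
            index=self.names,
        )


@dataclass
class TransitionTable:
    both: int
    six_only: int
    thirtysix_only: int
    neither: int

    @property
    def month6_total(self) -> int:
        return self.both + self.six_only

    @property
    def month36_total(self) -> int:
        return self.both + self.thirtysix_only

    @property
    def converters(self) -> int:
        return self.six_only + self.thirtysix_only

    @property
    def n(self) -> int:
        return self.both + self.six_only + self.thirtysix_only + self.neither


def domain_summary(test_z_by_domain: dict) -> tuple[dict, dict]:
    """Average test-specific z-scores into one summary z per domain.

    Missing (NaN) tests are dropped; an empty domain yields NaN with a
    zero count so the caller can flag it.  Returns (summary z per domain,
    number of tests used per domain).
    """
    zs, ns = {}, {}
    for domain, vals in test_z_by_domain.items():
        arr = np.asarray(vals, dtype=float)
        ok = np.isfinite(arr)
        ns[domain] = int(ok.sum())
        zs[domain] = float(arr[ok].mean()) if ok.any() else float("nan")
    return zs, ns


def psci_classify(domain_z, threshold: float = PSCI_THRESHOLD) -> int:
    """Impairment status: 1 iff any domain summary z <= threshold.

    The threshold is inclusive (a domain exactly at -1.5 classifies as
    impaired).  Non-finite domain scores are rejected — status would be
    undefined.
    """
    z = np.asarray(domain_z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("undefined status: non-finite domain z-score")
    return int(np.min(z) <= threshold)


def fit_logistic(y, X, names: list[str] | None = None) -> GLMFit:
    """Maximum-likelihood logistic regression with Wald inference.

    Fit by iteratively reweighted least squares (Newton); standard errors
    from the observed information; odds ratios and 95% CIs as exp
    transforms of the Wald interval.  Rank-deficient designs are rejected;
    diverging coefficients (perfect separation) raise SeparationError.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    try:
        res = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises on hard separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(se)) or np.any(np.abs(coef) > 30):
        raise SeparationError("diverging coefficients: (quasi-)separated data")
    ci = np.exp(np.column_stack([coef - 1.96 * se, coef + 1.96 * se]))
    return GLMFit(
        names=list(names),
        coef=coef,
        se=se,
        or_=np.exp(coef),
        ci95=ci,
        p=np.asarray(res.pvalues),
        loglik=float(res.llf),
        n_params=X.shape[1],
        n_obs=len(y),
    )


def lr_test(loglik_full: float, loglik_reduced: float, df_diff: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested models: chi2 = 2 * delta-loglik."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    if loglik_full < loglik_reduced - 1e-8:
        raise ValueError("nesting violated: full model has lower likelihood")
    chi2 = max(2.0 * (loglik_full - loglik_reduced), 0.0)
    return chi2, float(stats.chi2.sf(chi2, df_diff))


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection flags at q)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _whiten(M: np.ndarray) -> np.ndarray:
    """Return W with cov(M @ W) = I (symmetric inverse square root)."""
    S = np.cov(M, rowvar=False)
    S = np.atleast_2d(S)
    vals, vecs = np.linalg.eigh(S)
    if np.any(vals <= 1e-12):
        raise ValueError("covariance not positive definite (constant column?)")
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def cca_first(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
) -> CCAResult:
    """First canonical correlation with a row-permutation significance test.

    The first canonical pair comes from the SVD of the whitened
    cross-covariance; the null distribution is built by permuting the rows
    of Y and recomputing r1, with perm_p = (1 + #{r_perm >= r_obs}) /
    (n_perm + 1).  r1 is nonnegative by the sign convention on y-weights.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q:
        raise ValueError("need more observations than total variables")
    if np.any(X.std(axis=0) == 0) or np.any(Y.std(axis=0) == 0):
        raise ValueError("constant column in X or Y")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Wx = _whiten(Xc)
    Wy = _whiten(Yc)
    Xw = Xc @ Wx
    Yw = Yc @ Wy
    C = Xw.T @ Yw / (n - 1)
    u, s, vt = np.linalg.svd(C)
    r1 = float(min(s[0], 1.0))
    x_w = Wx @ u[:, 0]
    y_w = Wy @ vt[0]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sp = np.linalg.svd(Xw[perm].T @ Yw / (n - 1), compute_uv=False)[0]
        if sp >= r1:
            exceed += 1
    perm_p = (1 + exceed) / (n_perm + 1)
    return CCAResult(r1=r1, x_weights=x_w, y_weights=y_w, perm_p=perm_p, n_perm=n_perm)


# --------------------------------------------------------------------------
# random-intercept logistic model
# --------------------------------------------------------------------------

def _mixed_loglik(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    weights: np.ndarray,
    newton_steps: int = 6,
) -> float:
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    The scalar random intercept b_i ~ N(0, sigma^2) is integrated out per
    subject.  Quadrature is adaptive: nodes are re-centered at each
    subject's posterior mode and re-scaled by the Laplace curvature, so a
    modest node count covers the integrand even for extreme subjects.
    """
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta = X @ beta
    # per-subject Newton search for the integrand mode
    b = np.zeros(n_groups)
    for _ in range(newton_steps):
        mu = expit(eta + b[groups])
        grad = np.bincount(groups, weights=y - mu, minlength=n_groups) - b / sigma**2
        curv = -np.bincount(groups, weights=mu * (1 - mu), minlength=n_groups) - 1.0 / sigma**2
        b = b - grad / curv
    tau = 1.0 / np.sqrt(-curv)  # Laplace scale at the mode
    # adapted nodes: b_iq = mode_i + sqrt(2) tau_i z_q
    bq = b[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    # log integrand h(b) = sum_t [y*eta_b - log(1+e^eta_b)] + log N(b; 0, sigma^2)
    eta_q = eta[:, None] + bq[groups]  # (n_obs, Q)
    ll_obs = y[:, None] * eta_q - np.logaddexp(0.0, eta_q)
    h = np.zeros((n_groups, nodes.size))
    np.add.at(h, groups, ll_obs)
    h += -0.5 * (bq / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    # integral: sqrt(2) tau_i sum_q w_q exp(z_q^2) exp(h_iq)
    log_terms = h + np.log(weights)[None, :] + nodes[None, :] ** 2
    log_L = 0.5 * np.log(2.0) + np.log(tau) + logsumexp(log_terms, axis=1)
    return float(log_L.sum())


def fit_logistic_mixed(
    table: pd.DataFrame,
    outcome: str = "psci",
    factor: str = "loading",
    time: str = "time",
    covariates: tuple[str, ...] = ("age", "education"),
    group: str = "subject_id",
    n_nodes: int = 15,
) -> MixedFit:
    """Random-intercept logistic model for repeated cognitive status.

    Fixed effects: intercept, factor loading, time (coded 0 = month 6,
    1 = month 36), factor x time interaction, and covariates; one normal
    random intercept per participant.  The marginal likelihood is
    maximized with the random-intercept SD on the log scale; Wald tests
    use the numerically evaluated observed information.  Subjects missing
    one timepoint contribute their available observations.
    """
    df = table.dropna(subset=[outcome, factor, time, *covariates]).copy()
    y = df[outcome].to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("outcome has zero variance")
    subj, groups = np.unique(df[group].to_numpy(), return_inverse=True)
    t = df[time].to_numpy(dtype=float)
    f = df[factor].to_numpy(dtype=float)
    names = ["intercept", factor, time, f"{factor}:{time}", *covariates]
    X = np.column_stack(
        [np.ones(len(df)), f, t, f * t] + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    start = np.zeros(X.shape[1] + 1)
    try:
        plain = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if np.all(np.isfinite(plain.params)) and np.abs(plain.params).max() < 30:
            start[:-1] = plain.params
    except Exception:
        pass

    def nll(p):
        return -_mixed_loglik(p, X, y, groups, len(subj), nodes, weights)

    from scipy.optimize import minimize

    # the likelihood is flat in log sigma near the sigma -> 0 boundary, so a
    # single start can stall; try a near-degenerate and a moderate start and
    # keep the better optimum
    res = None
    for log_sigma0 in (np.log(0.05), np.log(1.0)):
        s = start.copy()
        s[-1] = log_sigma0
        r = minimize(nll, s, method="BFGS", options={"gtol": 1e-5, "maxiter": 500})
        if res is None or (np.isfinite(r.fun) and r.fun < res.fun):
            res = r
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"mixed model failed to converge: {res.message}")
    H = numdiff.approx_hess(res.x, nll)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full_like(res.x, np.nan)
    coef = res.x[:-1]
    se = se_all[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = coef / se
    p = 2 * stats.norm.sf(np.abs(zvals))
    return MixedFit(
        names=names,
        coef=coef,
        se=se,
        or_=np.exp(coef),
        p=p,
        re_var=float(np.exp(res.x[-1]) ** 2),
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_subjects=len(subj),
    )


def transition_table(psci6, psci36) -> TransitionTable:
    """Cross-classify impairment status at months 6 and 36."""
    a = np.asarray(psci6, dtype=int)
    b = np.asarray(psci36, dtype=int)
    if a.shape != b.shape:
        raise ValueError("timepoint vectors differ in length")
    if set(np.unique(a)) - {0, 1} or set(np.unique(b)) - {0, 1}:
        raise ValueError("status vectors must be binary")
    return TransitionTable(
        both=int(np.sum((a == 1) & (b == 1))),
        six_only=int(np.sum((a == 1) & (b == 0))),
        thirtysix_only=int(np.sum((a == 0) & (b == 1))),
        neither=int(np.sum((a == 0) & (b == 0))),
    )
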