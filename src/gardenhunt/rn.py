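"""Royle-Nichols latent-abundance occupancy model.

The model explains heterogeneity in detection/non-detection data through a
latent site abundance: site i holds ``N_i ~ Poisson(lambda_i)`` animals with
``log lambda_i = x_i . beta`` (site covariates), each individual is detected
on visit j with probability ``r_ij`` where ``logit r_ij = w_ij . alpha``
(observation covariates: survey effort, standardized visit date, off-camera
track density), and the visit-level detection probability is

    p_ij = 1 - (1 - r_ij) ** N_i.

The marginal likelihood of a site's detection history sums the Poisson prior
over ``N = 0..K`` for a truncation bound K chosen well above any plausible
abundance; a truncation-stability check (log-likelihood shift when K is
doubled) is run after every fit.  Missing visits (camera absent or
inoperative, effort NA) contribute nothing to the site product.

Effort enters as an ordinary detection covariate on the logit scale, not as
an offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .survey import DetectionHistory

__all__ = [
    "RNSpec",
    "RNDesign",
    "RNFit",
    "DETECTION_TERMS",
    "SITE_TERMS",
    "detection_prob",
    "site_loglik",
    "build_design",
    "fit_rn",
    "predict_lambda",
    "simulate_y",
]

DETECTION_TERMS = ("date", "effort", "tracks_dens")
SITE_TERMS = ("tree_buffer", "tree_buffer2", "dist_river", "dist_conuco")


@dataclass(frozen=True)
class RNSpec:
    """A candidate model: which covariates enter detection and abundance.

    Intercepts are always present and not listed.  ``tree_buffer2`` (the
    square of standardized tree cover) may only appear together with the
    linear term (hierarchical polynomial).
    """

    species: str = ""
    detection_terms: tuple[str, ...] = ()
    site_terms: tuple[str, ...] = ()

    def __post_init__(self):
        for t in self.detection_terms:
            if t not in DETECTION_TERMS:
                raise ValueError(f"unknown detection term {t!r}")
        for t in self.site_terms:
            if t not in SITE_TERMS:
                raise ValueError(f"unknown site term {t!r}")
        if "tree_buffer2" in self.site_terms and "tree_buffer" not in self.site_terms:
            raise ValueError("tree_buffer2 requires tree_buffer (hierarchy)")

    @property
    def n_params(self) -> int:
        return 2 + len(self.detection_terms) + len(self.site_terms)

    def label(self) -> str:
        det = "+".join(("1",) + self.detection_terms)
        lam = "+".join(("1",) + self.site_terms)
        return f"p({det}) lam({lam})"


@dataclass
class RNDesign:
    """Arrays the likelihood consumes.

    ``W`` is the (M, J, 1+Pd) detection design (leading intercept column),
    zeroed at missing cells; ``X`` the (M, 1+Ps) site design; ``y`` the
    detection matrix with NaN at missing cells.
    """

    y: np.ndarray
    W: np.ndarray
    X: np.ndarray
    det_names: tuple[str, ...]
    site_names: tuple[str, ...]

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.y)


def detection_prob(r: float, N: int) -> float:
    """Visit detection probability for N independent individuals."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if N < 0:
        raise ValueError("N must be a non-negative integer")
    return 1.0 - (1.0 - r) ** N


def build_design(
    spec: RNSpec, history: DetectionHistory, covariates: pd.DataFrame
) -> RNDesign:
    """Assemble design arrays for one species and candidate model.

    ``covariates`` is indexed by camera_id (or holds a camera_id column) and
    must already be standardized; it supplies the site terms and the
    site-level detection covariate ``track_dens``.  Visit-level detection
    covariates (``effort``, ``date``) come from the history.
    """
    cov = (
        covariates.set_index("camera_id")
        if "camera_id" in covariates.columns
        else covariates
    )
    cov = cov.loc[history.sites]
    for c in cov.columns:
        vals = cov[c].to_numpy(float)
        if not np.isfinite(vals).all():
            bad = [history.sites[i] for i in np.flatnonzero(~np.isfinite(vals))]
            raise ValueError(f"non-finite covariate {c!r} at site(s) {bad}")

    M, J = history.y.shape
    layers = [np.ones((M, J))]
    for t in spec.detection_terms:
        if t == "date":
            layers.append(history.date)
        elif t == "effort":
            layers.append(history.effort)
        else:  # tracks_dens
            layers.append(np.tile(cov["track_dens"].to_numpy(float)[:, None], (1, J)))
    W = np.stack(layers, axis=-1)
    W[np.isnan(history.y)] = 0.0
    if np.isnan(W).any():
        raise ValueError("NaN detection covariate at an observed visit")

    cols = [np.ones(M)]
    tree = cov["tree_buffer"].to_numpy(float) if "tree_buffer" in cov else None
    for t in spec.site_terms:
        if t == "tree_buffer2":
            cols.append(tree**2)
        else:
            cols.append(cov[t].to_numpy(float))
    X = np.column_stack(cols)
    return RNDesign(
        y=history.y.astype(float),
        W=W,
        X=X,
        det_names=("(Intercept)",) + spec.detection_terms,
        site_names=("(Intercept)",) + spec.site_terms,
    )


# ---------------------------------------------------------------------------
# likelihood


_LOGFACT: dict[int, np.ndarray] = {}


def _log_factorials(K: int) -> np.ndarray:
    if K not in _LOGFACT:
        _LOGFACT[K] = gammaln(np.arange(K + 1, dtype=float) + 1.0)
    return _LOGFACT[K]


_NEG_BIG = -1e30  # finite stand-in for log 0, keeps BLAS paths NaN-free


def _logjoint(alpha, beta, design: RNDesign, K: int):
    """(K+1, M) log joint of (N, y_i) plus intermediates reused by the score.

    Non-detection cells factor as ``(1-r)^N`` whose logs add across visits,
    so they collapse to one per-site sum before the N loop; only detection
    cells (sparse in camera-trap data) need the full (K+1) x cell grid.
    """
    y = design.y
    wlin = design.W @ alpha  # (M, J)
    xlin = np.clip(design.X @ beta, -500.0, 30.0)  # (M,)
    lam = np.exp(xlin)
    r = expit(wlin)
    log1mr = np.log1p(-r)
    N = np.arange(K + 1, dtype=float)

    zero_cells = y == 0.0
    A = np.where(zero_cells, log1mr, 0.0).sum(axis=1)  # (M,)
    cond = N[:, None] * (A + xlin)[None]  # Poisson N log lam folded in
    cond -= lam[None]
    cond -= _log_factorials(K)[:, None]

    ii, jj = np.nonzero(y == 1.0)
    ln_q = None
    if ii.size:
        ln_q = N[:, None] * log1mr[ii, jj][None]  # (K+1, c)
        with np.errstate(divide="ignore"):
            ln_p = np.log(-np.expm1(ln_q))  # -inf at N=0
        ln_p[0] = _NEG_BIG
        ind = np.zeros((ii.size, y.shape[0]))
        ind[np.arange(ii.size), ii] = 1.0
        cond += ln_p @ ind
    return cond, (lam, r, zero_cells, ii, jj, ln_q, N)


def _site_logliks(
    alpha: np.ndarray, beta: np.ndarray, design: RNDesign, K: int
) -> np.ndarray:
    """Per-site marginal log-likelihoods, vectorized over N = 0..K."""
    lj, _ = _logjoint(np.asarray(alpha, float), np.asarray(beta, float), design, K)
    return logsumexp(lj, axis=0)


def site_loglik(
    y_row, w_row, x_row, alpha, beta, K: int
) -> float:
    """Marginal log-likelihood contribution of one site.

    ``w_row`` is the (J, 1+Pd) detection design for the site's visits
    (intercept column included), ``x_row`` the (1+Ps,) site design row.
    Missing visits (NaN in ``y_row``) are skipped.
    """
    y = np.asarray(y_row, float).reshape(1, -1)
    W = np.asarray(w_row, float).reshape(1, y.shape[1], -1).copy()
    W[np.isnan(y)] = 0.0
    X = np.asarray(x_row, float).reshape(1, -1)
    if not (np.isfinite(W).all() and np.isfinite(X).all()):
        raise ValueError("non-finite covariates for site")
    d = RNDesign(y=y, W=W, X=X, det_names=(), site_names=())
    return float(_site_logliks(np.asarray(alpha, float), np.asarray(beta, float), d, K)[0])


@dataclass
class RNFit:
    """A fitted Royle-Nichols model."""

    spec: RNSpec
    alpha: np.ndarray
    beta: np.ndarray
    loglik: float
    K: int
    vcov: np.ndarray | None
    n_sites: int
    converged: bool
    design: RNDesign = field(repr=False, default=None)
    boundary: bool = False
    trunc_delta: float = np.nan

    @property
    def k(self) -> int:
        return len(self.alpha) + len(self.beta)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])

    @property
    def param_names(self) -> list[str]:
        return [f"p:{n}" for n in self.design.det_names] + [
            f"lam:{n}" for n in self.design.site_names
        ]

    def se(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(self.k, np.nan)
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def coef(self, term: str) -> tuple[float, float]:
        """(estimate, variance) of a named term, e.g. ``"lam:dist_conuco"``."""
        i = self.param_names.index(term)
        var = np.nan if self.vcov is None else float(self.vcov[i, i])
        return float(self.params[i]), var


def default_truncation(y: np.ndarray, r_guess: float = 0.2) -> int:
    """Truncation bound: three times a method-of-moments abundance guess.

    The per-site detection total divided by a nominal per-individual
    detection rate is a crude moment guess at the largest site abundance;
    the bound is three times that, never below 50.  Stability is verified
    after fitting by doubling K.
    """
    max_det = int(np.nanmax(np.nansum(np.nan_to_num(y), axis=1), initial=0))
    guess = max(1, max_det) / r_guess
    return int(max(50, np.ceil(3 * guess)))


def _loglik_grad(
    alpha: np.ndarray, beta: np.ndarray, design: RNDesign, K: int
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and its exact gradient.

    Uses the posterior over the latent abundance: with posterior weights
    ``w_N(i)``, the score in beta is ``X' (E[N|y] - lambda)`` and the score
    in alpha accumulates ``d log f_ij / d eta_ij`` over cells
    (``-E[N|y] r`` for non-detections, ``r E[N q^N / (1-q^N)]`` with
    ``q = 1-r`` for detections).
    """
    logjoint, (lam, r, zero_cells, ii, jj, ln_q, N) = _logjoint(
        np.asarray(alpha, float), np.asarray(beta, float), design, K
    )
    m = logjoint.max(axis=0)
    w = np.exp(logjoint - m[None])
    denom = w.sum(axis=0)
    ll_i = m + np.log(denom)
    ll = float(ll_i.sum())
    wpost = w / denom[None]  # (K+1, M)
    EN = N @ wpost  # (M,)

    grad_beta = design.X.T @ (EN - lam)

    G = np.where(zero_cells, -EN[:, None] * r, 0.0)  # d ll / d eta_ij
    if ii.size:
        qN = np.exp(ln_q)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = N[:, None] * qN / (-np.expm1(ln_q))
        t[0] = 0.0  # N = 0 carries zero posterior mass for a detected site
        s = (wpost[:, ii] * t).sum(axis=0)
        G[ii, jj] = r[ii, jj] * s
    grad_alpha = np.einsum("mj,mjp->p", G, design.W)
    return ll, np.concatenate([grad_alpha, grad_beta])


def _negloglik_factory(design: RNDesign, K: int, n_alpha: int, with_grad: bool = True):
    if with_grad:
        def nll(theta: np.ndarray):
            alpha, beta = theta[:n_alpha], theta[n_alpha:]
            ll, g = _loglik_grad(alpha, beta, design, K)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(theta)
            return -ll, -g
    else:
        def nll(theta: np.ndarray) -> float:
            alpha, beta = theta[:n_alpha], theta[n_alpha:]
            ll = _site_logliks(alpha, beta, design, K).sum()
            return -ll if np.isfinite(ll) else 1e12

    return nll


def _hessian_from_grad(grad_f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central differences of an exact gradient; symmetrized."""
    k = x.size
    H = np.empty((k, k))
    hs = h * np.maximum(1.0, np.abs(x))
    for a in range(k):
        e = np.zeros(k)
        e[a] = hs[a]
        H[:, a] = (grad_f(x + e) - grad_f(x - e)) / (2 * hs[a])
    return 0.5 * (H + H.T)


def fit_rn(
    spec: RNSpec,
    history: DetectionHistory,
    covariates: pd.DataFrame,
    K: int | None = None,
    n_starts: int = 5,
    seed: int = 0,
    start: np.ndarray | None = None,
    compute_vcov: bool = True,
    gtol: float = 1e-8,
    check_truncation: bool = True,
) -> RNFit:
    """Maximum-likelihood fit by quasi-Newton optimization.

    Runs ``n_starts`` jittered initializations (seed-controlled) and keeps
    the best optimum; the coefficient covariance is the inverse observed
    information (central-difference Hessian) at the optimum.  A fit is
    flagged ``converged=False`` when no start reaches a finite optimum with
    a usable curvature; downstream model selection drops such fits.
    """
    design = build_design(spec, history, covariates)
    if K is None:
        K = default_truncation(design.y)
    n_alpha = design.W.shape[-1]
    nll = _negloglik_factory(design, K, n_alpha)

    obs = ~design.mask
    if obs.sum() == 0:
        raise ValueError("no observed visits")
    naive_p = float(np.nanmean(design.y[obs])) if obs.any() else 0.0
    r0 = np.clip(naive_p * 0.7 + 0.01, 0.01, 0.9)
    mean_det = float(np.nansum(design.y) / design.y.shape[0])
    x0 = np.zeros(spec.n_params)
    x0[0] = np.log(r0 / (1 - r0))
    x0[n_alpha] = np.log(max(mean_det, 0.05))

    rng = np.random.default_rng(seed)
    if start is not None:
        starts = [np.asarray(start, float)]
        starts += [starts[0] + rng.normal(0, 0.3, spec.n_params) for _ in range(n_starts - 1)]
    else:
        starts = [x0] + [x0 + rng.normal(0, 0.5, spec.n_params) for _ in range(n_starts - 1)]

    best = None
    for s in starts:
        res = minimize(nll, s, method="BFGS", jac=True,
                       options={"gtol": gtol, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    theta = best.x
    loglik = -best.fun
    converged = bool(np.isfinite(loglik))
    boundary = bool(theta[n_alpha] < -8.0)  # log lambda intercept at -inf edge

    vcov = None
    if compute_vcov and converged and not boundary:
        H = _hessian_from_grad(lambda t: nll(t)[1], theta)
        try:
            vcov = np.linalg.inv(H)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < -1e-6):
                converged = False
                vcov = None
        except np.linalg.LinAlgError:
            converged = False

    fit = RNFit(
        spec=spec,
        alpha=theta[:n_alpha],
        beta=theta[n_alpha:],
        loglik=loglik,
        K=K,
        vcov=vcov,
        n_sites=design.y.shape[0],
        converged=converged,
        design=design,
        boundary=boundary,
    )
    if check_truncation:
        ll2 = _site_logliks(fit.alpha, fit.beta, design, 2 * K).sum()
        fit.trunc_delta = float(abs(ll2 - loglik))
        if fit.trunc_delta > 1e-4:
            warnings.warn(
                f"truncation bound K={K} unstable (doubling shifts loglik by "
                f"{fit.trunc_delta:.2e}); increase K",
                stacklevel=2,
            )
    return fit


def predict_lambda(
    fit: RNFit, covariate_rows: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Per-site expected abundance with delta-method standard errors.

    ``lambda_i = exp(x_i . beta)``; ``SE(lambda_i) = lambda_i *
    sqrt(x_i' V x_i)``.  Covariate values far outside the training range
    (over 5 SD) trigger an extrapolation warning.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if isinstance(covariate_rows, pd.DataFrame):
        cov = (
            covariate_rows.set_index("camera_id")
            if "camera_id" in covariate_rows.columns
            else covariate_rows
        )
        cols = [np.ones(len(cov))]
        tree = cov["tree_buffer"].to_numpy(float) if "tree_buffer" in cov else None
        for t in fit.spec.site_terms:
            cols.append(tree**2 if t == "tree_buffer2" else cov[t].to_numpy(float))
        X = np.column_stack(cols)
        index = cov.index
    else:
        X = np.asarray(covariate_rows, float)
        index = pd.RangeIndex(len(X))

    Xtrain = fit.design.X
    for c in range(1, X.shape[1]):
        mu, sd = Xtrain[:, c].mean(), Xtrain[:, c].std(ddof=1) or 1.0
        if np.any(np.abs(X[:, c] - mu) > 5 * sd):
            warnings.warn(
                f"extrapolating site term {fit.design.site_names[c]!r} beyond "
                f"5 SD of the training range",
                stacklevel=2,
            )
    lam = np.exp(X @ fit.beta)
    if fit.vcov is not None:
        Vb = fit.vcov[len(fit.alpha):, len(fit.alpha):]
        se = lam * np.sqrt(np.einsum("ij,jk,ik->i", X, Vb, X).clip(0))
    else:
        se = np.full(len(lam), np.nan)
    return pd.DataFrame({"lambda": lam, "se": se}, index=index)


def simulate_y(
    rng: np.random.Generator,
    alpha: np.ndarray,
    beta: np.ndarray,
    design: RNDesign,
) -> np.ndarray:
    """Draw a detection matrix from the RN process on a given design.

    N_i ~ Poisson(exp(x_i.beta)); y_ij ~ Bernoulli(1-(1-r_ij)^N_i) at
    observed cells, NaN at masked cells.
    """
    lam = np.exp(np.clip(design.X @ np.asarray(beta, float), -500, 30))
    r = expit(design.W @ np.asarray(alpha, float))
    N = rng.poisson(lam)
    p = 1.0 - (1.0 - r) ** N[:, None]
    y = (rng.random(design.y.shape) < p).astype(float)
    y[design.mask] = np.nan
    return y
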