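"""Likelihood machinery for joint ctDNA-burden and tissue-of-origin inference.

Model
-----
A plasma cfDNA methylation level at cluster k is a two-component mixture
``x_k = (1 - theta) v_k + theta u_k`` with v_k ~ Beta(alpha_k0, beta_k0)
(normal plasma) and u_k ~ Beta(alpha_kt, beta_kt) (tumor class t), where
theta is the circulating-tumor-DNA fraction.  The density of x_k, written
psi(x | theta, t), is the (scaled) convolution of the two Beta densities.
Sequencing observes counts (m_k, n_k) with m_k ~ Binomial(n_k, x_k), so the
per-cluster marginal is

    f(m | theta, t, n) = E_{v,u}[ Binomial(m | n, (1-theta) v + theta u) ].

Assuming independent clusters, the sample log-likelihood is the sum of
log f over the panel's selected features; (theta, t) are estimated by a
grid search over theta in {0, 1/J, ..., (J-1)/J} and t in 1..T.  The
cancer call uses the per-feature-normalized log-likelihood gain

    lambda = (1/K_used) [ max log L(theta, t) - log L(theta = 0) ] >= 0,

thresholded (default 0.023) to decide cancer vs non-cancer.

Numerics
--------
Two independent evaluation routes are provided.

* An exact route: expanding x^m (1-x)^(n-m) binomially in the mixture
  gives f as a finite sum of nonnegative terms built from joint Beta
  moments E[v^a (1-v)^b] = B(alpha+a, beta+b) / B(alpha, beta), which obey
  a stable two-term recurrence.  No quadrature, no cancellation; this is
  what :func:`grid_mle` uses, with the moment tables cached per panel in
  :class:`PanelLikelihood`.
* A quadrature route (:func:`cluster_loglik`, :func:`psi_density`):
  Simpson's rule after transforming each Beta variable through its CDF, so
  the integrand is bounded even for endpoint-singular shapes (alpha < 1 or
  beta < 1).  This route is the in-package cross-check of the exact one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate
from scipy.special import comb
from scipy.stats import beta as beta_dist
from scipy.stats import binom as binom_dist

from .io import SeqProfile
from .reference import ReferencePanel

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap

__all__ = [
    "ThetaGrid",
    "InferenceResult",
    "InferenceError",
    "PanelLikelihood",
    "mixture_level",
    "psi_density",
    "cluster_loglik",
    "total_loglik",
    "grid_mle",
    "predict_many",
    "beta_joint_moments",
    "DEFAULT_LAMBDA_THRESHOLD",
]

DEFAULT_LAMBDA_THRESHOLD = 0.023
_F_FLOOR = 1e-320  # probability floor before taking logs


class InferenceError(ValueError):
    """Raised when a profile carries no usable features."""


@dataclass(frozen=True)
class ThetaGrid:
    """The burden search grid {0, 1/J, 2/J, ..., (J-1)/J}."""

    J: int = 100

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValueError("grid resolution J must be >= 2")

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.J) / self.J


@dataclass
class InferenceResult:
    """Outcome of the grid-search MLE for one plasma sample."""

    sample_id: str
    theta_hat: float
    t_hat: int | None
    lambda_score: float
    is_cancer: bool
    used_features: int
    loglik_grid: np.ndarray  # shape (T, J): tumor classes 1..T by theta grid
    thetas: np.ndarray
    ties: list[tuple[float, int]] = field(default_factory=list)

    @property
    def predicted_label(self) -> int:
        """Six-class label: 0 for non-cancer, else the tumor class."""
        return self.t_hat if (self.is_cancer and self.t_hat is not None) else 0


def mixture_level(v: float, u: float, theta: float) -> float:
    """Plasma methylation level as the burden-weighted mix of normal and tumor."""
    return (1.0 - theta) * v + theta * u


# ------------------------------------------------------------ exact route


def beta_joint_moments(
    alpha: np.ndarray | float, beta: np.ndarray | float, amax: int, bmax: int
) -> np.ndarray:
    """Joint moments E[v^a (1-v)^b], v ~ Beta(alpha, beta), for a<=amax, b<=bmax.

    Returned array has shape ``alpha.shape + (amax+1, bmax+1)``.  Uses the
    recurrence  M[a,b] = M[a-1,b] * (alpha+a-1)/(alpha+beta+a+b-1)  (and its
    b-analogue), which involves only nonnegative factors < 1.
    """
    a_arr = np.atleast_1d(np.asarray(alpha, dtype=float))
    b_arr = np.atleast_1d(np.asarray(beta, dtype=float))
    a_arr, b_arr = np.broadcast_arrays(a_arr, b_arr)
    s = a_arr + b_arr
    b_idx = np.arange(bmax + 1, dtype=float)
    M = np.empty(a_arr.shape + (amax + 1, bmax + 1), dtype=float)
    M[..., 0, 0] = 1.0
    if bmax > 0:
        M[..., 0, 1:] = np.cumprod(
            (b_arr[..., None] + b_idx[:-1]) / (s[..., None] + b_idx[:-1]), axis=-1
        )
    for a in range(1, amax + 1):
        M[..., a, :] = M[..., a - 1, :] * (
            (a_arr[..., None] + a - 1) / (s[..., None] + a - 1 + b_idx)
        )
    if np.isscalar(alpha) and np.isscalar(beta):
        return M[0]
    return M


def _pair_weights(m: int, n: int, thetas: np.ndarray) -> np.ndarray:
    """W[q, i, j] = C(m,i) C(n-m,j) (1-theta_q)^(i+j) theta_q^(n-i-j).

    These are the mixture expansion weights of x^m (1-x)^(n-m): writing
    x = (1-theta) v + theta u and 1-x = (1-theta)(1-v) + theta (1-u) and
    expanding both powers binomially gives only nonnegative terms.
    """
    i = np.arange(m + 1)
    j = np.arange(n - m + 1)
    ipj = i[:, None] + j[None, :]
    cij = comb(m, i)[:, None] * comb(n - m, j)[None, :]
    omt = (1.0 - thetas)[:, None, None] ** ipj[None, :, :]
    th = thetas[:, None, None] ** (n - ipj)[None, :, :]
    return cij[None, :, :] * omt * th


def _exact_f(m: int, n: int, theta: float, normal, tumor) -> float:
    """Exact per-cluster marginal f(m | theta, t, n) via joint Beta moments."""
    if n == 0:
        return 1.0
    W = _pair_weights(m, n, np.asarray([theta], dtype=float))[0]
    Jv = beta_joint_moments(float(normal[0]), float(normal[1]), m, n - m)
    Ju = beta_joint_moments(float(tumor[0]), float(tumor[1]), m, n - m)
    Ju_f = Ju[::-1, ::-1]  # index (i, j) -> E[u^(m-i) (1-u)^(n-m-j)]
    return float(comb(n, m, exact=False) * np.sum(W * Jv * Ju_f))


@_njit(cache=True)
def _ll_kernel(m, n, alphas, betas, thetas, combt, ll_out):  # pragma: no cover
    """Accumulate log-likelihood over (tumor class, theta) per cluster.

    For each usable cluster the joint Beta moment rectangles of the normal
    and tumor classes are built by their two-term recurrences, combined
    into the theta-polynomial coefficients G[s], and the polynomial is
    evaluated on the theta grid in a log-safe normalized form.  Compiled
    by numba; the numpy implementation in PanelLikelihood computes the
    same quantity and serves as its in-package cross-check.
    """
    n_class, K = alphas.shape
    Q = thetas.shape[0]
    nmax = 0
    for k in range(K):
        if n[k] > nmax:
            nmax = n[k]
    S = nmax + 1
    OM = np.empty((Q, S))
    TH = np.empty((Q, S))
    for q in range(Q):
        OM[q, 0] = 1.0
        TH[q, 0] = 1.0
        for s in range(1, S):
            OM[q, s] = OM[q, s - 1] * (1.0 - thetas[q])
            TH[q, s] = TH[q, s - 1] * thetas[q]
    A = np.empty((S, S))
    B = np.empty((S, S))
    G = np.empty(S)
    log_floor = -736.0  # log(1e-320)
    for k in range(K):
        nk = int(n[k])
        if nk < 1:
            continue
        mk = int(m[k])
        rm = nk - mk
        a0 = alphas[0, k]
        b0 = betas[0, k]
        s0 = a0 + b0
        A[0, 0] = 1.0
        for j in range(1, rm + 1):
            A[0, j] = A[0, j - 1] * (b0 + j - 1) / (s0 + j - 1)
        for i in range(1, mk + 1):
            for j in range(rm + 1):
                A[i, j] = A[i - 1, j] * (a0 + i - 1) / (s0 + i + j - 1)
        lcnm = np.log(combt[nk, mk])
        for t in range(1, n_class):
            at = alphas[t, k]
            bt = betas[t, k]
            st = at + bt
            B[0, 0] = 1.0
            for j in range(1, rm + 1):
                B[0, j] = B[0, j - 1] * (bt + j - 1) / (st + j - 1)
            for i in range(1, mk + 1):
                for j in range(rm + 1):
                    B[i, j] = B[i - 1, j] * (at + i - 1) / (st + i + j - 1)
            for s in range(nk + 1):
                G[s] = 0.0
            for i in range(mk + 1):
                ci = combt[mk, i]
                for j in range(rm + 1):
                    G[i + j] += ci * combt[rm, j] * A[i, j] * B[mk - i, rm - j]
            gmax = 0.0
            for s in range(nk + 1):
                if G[s] > gmax:
                    gmax = G[s]
            if gmax <= 0.0:
                for q in range(Q):
                    ll_out[t - 1, q] += log_floor
                continue
            lscale = lcnm + np.log(gmax)
            for q in range(Q):
                acc = 0.0
                for s in range(nk + 1):
                    acc += (G[s] / gmax) * OM[q, s] * TH[q, nk - s]
                if acc > 0.0:
                    lf = lscale + np.log(acc)
                    if lf < log_floor:
                        lf = log_floor
                else:
                    lf = log_floor
                ll_out[t - 1, q] += lf


def _comb_table(nmax: int) -> np.ndarray:
    """Pascal triangle C(a, b) as floats, a, b <= nmax."""
    t = np.zeros((nmax + 1, nmax + 1))
    t[:, 0] = 1.0
    for a in range(1, nmax + 1):
        t[a, 1 : a + 1] = t[a - 1, : a] + t[a - 1, 1 : a + 1]
    return t


class PanelLikelihood:
    """Cached per-panel likelihood evaluator over a theta grid.

    Precomputes joint Beta moment tables up to order ``pmax`` for every
    class and selected feature; profiles sharing a panel and grid then cost
    only the (grouped) expansion sums.  Clusters observed with n > pmax
    fall back to on-demand moment computation.
    """

    def __init__(
        self,
        panel: ReferencePanel,
        grid: ThetaGrid | None = None,
        thetas: np.ndarray | None = None,
        pmax: int = 48,
        min_coverage: int = 1,
    ):
        if thetas is None:
            thetas = (grid or ThetaGrid()).values
        self.thetas = np.asarray(thetas, dtype=float)
        if self.thetas.ndim != 1 or self.thetas.size == 0:
            raise ValueError("thetas must be a non-empty 1-D array")
        if np.any((self.thetas < 0) | (self.thetas >= 1)):
            raise ValueError("theta values must lie in [0, 1)")
        self.panel = panel
        self.features = list(panel.selected_features)
        self.index = {cid: k for k, cid in enumerate(self.features)}
        self.pmax = int(pmax)
        self.min_coverage = max(1, int(min_coverage))
        self.classes = sorted(panel.models)
        self.n_tumor = self.classes[-1]
        self._ab = {}
        for t in self.classes:
            ab = np.array([panel.models[t].params[cid] for cid in self.features], dtype=float)
            self._ab[t] = ab
        self._alpha_stack = np.stack([self._ab[t][:, 0] for t in self.classes])
        self._beta_stack = np.stack([self._ab[t][:, 1] for t in self.classes])
        self._jm: dict[int, np.ndarray] = {}  # lazy cache for the numpy path
        self._combt: np.ndarray | None = None

    def align(self, profile: SeqProfile) -> tuple[np.ndarray, np.ndarray]:
        """(m, n) count arrays aligned to the panel's feature order.

        Features absent from the profile get n = 0 (no information).
        """
        m = np.zeros(len(self.features), dtype=np.int64)
        n = np.zeros(len(self.features), dtype=np.int64)
        for cid, (mm, nn) in profile.counts.items():
            k = self.index.get(cid)
            if k is not None:
                m[k], n[k] = mm, nn
        return m, n

    def _group_moments(self, ks: np.ndarray, S: int) -> np.ndarray:
        """Joint moments E[.^a (1-.)^b], a,b < S, for every class, stacked.

        Served from the per-panel cache when the order fits, otherwise
        computed on demand with the vectorized recurrence.
        """
        if S - 1 <= self.pmax:
            if not self._jm:
                for t in self.classes:
                    ab = self._ab[t]
                    self._jm[t] = beta_joint_moments(ab[:, 0], ab[:, 1], self.pmax, self.pmax)
            return np.stack([self._jm[t][ks, :S, :S] for t in self.classes])
        a = np.stack([self._ab[t][ks, 0] for t in self.classes])
        b = np.stack([self._ab[t][ks, 1] for t in self.classes])
        return beta_joint_moments(a, b, S - 1, S - 1)

    def loglik_grid(self, m: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, int]:
        """Log-likelihood over (tumor class, theta) for aligned count arrays.

        Returns ``(ll, K_used)`` where ``ll[t-1, q]`` is the joint
        log-likelihood for tumor class t at ``thetas[q]``, summed over the
        usable features (n >= min_coverage); K_used is their count.

        Per cluster the marginal f(m | theta, t, n) is a polynomial of
        degree n in theta with nonnegative coefficients,

            f = C(n,m) * sum_s G[s] (1-theta)^s theta^(n-s),
            G[s] = sum_{i+j=s} C(m,i) C(n-m,j) E[v^i (1-v)^j]
                                              * E[u^(m-i) (1-u)^(n-m-j)],

        so the coefficients are built once per cluster (antidiagonal sums
        over the joint-moment tensors) and the whole theta grid is then a
        single matrix product.
        """
        m = np.asarray(m, dtype=np.int64)
        n = np.asarray(n, dtype=np.int64)
        usable = n >= self.min_coverage
        K_used = int(usable.sum())
        T, Q = self.n_tumor, self.thetas.size
        ll = np.zeros((T, Q), dtype=float)
        if K_used == 0:
            return ll, 0
        nmax = int(n.max())
        if nmax > 1000:
            raise ValueError(
                f"cluster coverage n={nmax} exceeds the supported maximum of "
                "1000 cytosines; aggregate or thin such clusters upstream"
            )
        if _HAVE_NUMBA:
            if self._combt is None or self._combt.shape[0] <= nmax:
                self._combt = _comb_table(max(nmax, 64))
            mm = np.where(usable, m, 0)
            nn_arr = np.where(usable, n, 0)
            _ll_kernel(
                mm, nn_arr, self._alpha_stack, self._beta_stack,
                self.thetas, self._combt, ll,
            )
            return ll, K_used
        th = self.thetas
        om = 1.0 - th
        ku = np.where(usable)[0]
        for nn in np.unique(n[ku]):
            ks = ku[n[ku] == nn]
            nn = int(nn)
            S = nn + 1
            mk = m[ks]
            i = np.arange(S)
            Jall = self._group_moments(ks, S)  # (T+1, k, S, S)
            Ci = comb(mk[:, None], i[None, :])  # zero where i > m_k
            Cj = comb((nn - mk)[:, None], i[None, :])
            D0 = Ci[:, :, None] * Cj[:, None, :] * Jall[0]
            # gather indices for E[u^(m-i) (1-u)^(n-m-j)]; out-of-range
            # entries are clipped but killed by the zero binomial factors
            ai = np.clip(mk[:, None] - i[None, :], 0, S - 1)
            bj = np.clip((nn - mk)[:, None] - i[None, :], 0, S - 1)
            kidx = np.arange(len(ks))[:, None, None]
            P = om[:, None] ** i[None, :] * th[:, None] ** (nn - i)[None, :]  # (Q, S)
            cnm = comb(nn, mk)
            for t in range(1, T + 1):
                D = D0 * Jall[t][kidx, ai[:, :, None], bj[:, None, :]]
                G = np.zeros((len(ks), S))
                for ii in range(S):
                    G[:, ii:] += D[:, ii, : S - ii]
                F = (G @ P.T) * cnm[:, None]  # (k, Q)
                ll[t - 1] += np.log(np.clip(F, _F_FLOOR, None)).sum(axis=0)
        return ll, K_used


# ------------------------------------------------------- quadrature route


def psi_density(
    x,
    theta: float,
    normal: tuple[float, float],
    tumor: tuple[float, float],
    method: str = "adaptive",
    n_nodes: int = 201,
    eps: float = 1e-6,
):
    """Density psi(x | theta, t) of the mixed level x = (1-theta) v + theta u.

    psi is the convolution of the two scaled Beta densities,

        psi(x) = 1/(1-theta) * int f_Beta((x - theta u)/(1-theta) | a0, b0)
                                    * f_Beta(u | at, bt) du,

    with u restricted to the subinterval where (x - theta u)/(1-theta)
    stays in [0, 1].  At theta = 0 it collapses to the normal Beta density,
    at theta = 1 (degenerate, no convolution) to the tumor density.

    ``method="adaptive"`` (default) uses adaptive quadrature per x node and
    handles endpoint-singular Betas; ``method="simpson"`` uses composite
    Simpson on ``n_nodes`` over the eps-clipped subinterval (faster, less
    accurate near singular endpoints).
    """
    a0, b0 = float(normal[0]), float(normal[1])
    at, bt = float(tumor[0]), float(tumor[1])
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    if theta == 0.0:
        out = beta_dist.pdf(xs, a0, b0)
    elif theta == 1.0:
        out = beta_dist.pdf(xs, at, bt)
    else:
        out = np.empty_like(xs)
        for idx, xv in np.ndenumerate(xs):
            lo = max(0.0, (xv - (1.0 - theta)) / theta)
            hi = min(1.0, xv / theta)
            if hi <= lo:
                out[idx] = 0.0
                continue

            def integrand(u):
                v = (xv - theta * u) / (1.0 - theta)
                v = np.clip(v, 0.0, 1.0)
                return beta_dist.pdf(v, a0, b0) * beta_dist.pdf(u, at, bt)

            if method == "adaptive":
                val, _ = integrate.quad(integrand, lo, hi, limit=200)
            elif method == "simpson":
                u = np.linspace(max(lo, eps), min(hi, 1.0 - eps), n_nodes)
                v = np.clip((xv - theta * u) / (1.0 - theta), eps, 1.0 - eps)
                f = beta_dist.pdf(v, a0, b0) * beta_dist.pdf(u, at, bt)
                val = integrate.simpson(f, x=u)
            else:
                raise ValueError(f"unknown method {method!r}")
            out[idx] = val / (1.0 - theta)
    out = np.maximum(out, 0.0)
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def cluster_loglik(
    m: int,
    n: int,
    theta: float,
    normal: tuple[float, float],
    tumor: tuple[float, float],
    n_nodes: int = 201,
) -> float:
    """Quadrature evaluation of log f(m | theta, t, n) for one cluster.

    The marginal is the double expectation over (v, u); substituting each
    Beta variable by its CDF gives a bounded integrand on the unit square,

        f = int_0^1 int_0^1 Binom(m | n, (1-theta) Q0(a) + theta Qt(b)) da db,

    (Q* = Beta quantile functions), evaluated with composite Simpson on an
    ``n_nodes`` x ``n_nodes`` grid whose nodes are clustered toward the
    endpoints by a quintic map (a = 6s^5 - 15s^4 + 10s^3); the clustering
    resolves the boundary layers the quantile functions create for
    concentrated or endpoint-singular Betas.  For n = 0 the cluster
    carries no information and the log-likelihood is 0.
    """
    if not 0 <= m <= n:
        raise ValueError(f"need 0 <= m <= n, got m={m}, n={n}")
    if n == 0:
        return 0.0
    s = np.linspace(0.0, 1.0, n_nodes)
    a = 6 * s**5 - 15 * s**4 + 10 * s**3
    da = 30 * s**2 * (1 - s) ** 2
    if theta >= 1.0:
        u = beta_dist.ppf(a, *map(float, tumor))
        f = integrate.simpson(binom_dist.pmf(m, n, np.clip(u, 0, 1)) * da, x=s)
    else:
        v = beta_dist.ppf(a, *map(float, normal))
        u = beta_dist.ppf(a, *map(float, tumor))
        X = np.clip((1.0 - theta) * v[:, None] + theta * u[None, :], 0.0, 1.0)
        P = binom_dist.pmf(m, n, X) * da[:, None] * da[None, :]
        f = integrate.simpson(integrate.simpson(P, x=s, axis=1), x=s)
    return float(np.log(max(f, _F_FLOOR)))


def total_loglik(
    profile: SeqProfile,
    panel: ReferencePanel,
    theta: float,
    t: int,
    method: str = "exact",
    min_coverage: int = 1,
    n_nodes: int = 201,
) -> float:
    """Joint log-likelihood of a sample at one (theta, t) point.

    Sums the per-cluster marginals over the panel's selected features,
    skipping clusters with n below ``min_coverage`` (they carry no usable
    signal and are excluded from K_used in the lambda normalization).
    """
    if t not in panel.models or t == 0:
        raise ValueError(f"t must be a tumor class 1..T, got {t}")
    total = 0.0
    for cid in panel.selected_features:
        m, n = profile.counts.get(cid, (0, 0))
        if n < min_coverage:
            continue
        ab0 = panel.models[0].params[cid]
        abt = panel.models[t].params[cid]
        if method == "exact":
            total += math.log(max(_exact_f(m, n, theta, ab0, abt), _F_FLOOR))
        elif method == "quadrature":
            total += cluster_loglik(m, n, theta, ab0, abt, n_nodes=n_nodes)
        else:
            raise ValueError(f"unknown method {method!r}")
    return total


# ------------------------------------------------------------- grid search


def grid_mle(
    profile: SeqProfile,
    panel: ReferencePanel,
    grid: ThetaGrid | None = None,
    lambda_threshold: float = DEFAULT_LAMBDA_THRESHOLD,
    min_coverage: int = 1,
    engine: PanelLikelihood | None = None,
) -> InferenceResult:
    """Grid-search maximum likelihood over (theta, t) plus the cancer call.

    Evaluates the joint log-likelihood at every theta on the grid (which
    includes 0) for every tumor class, takes the argmax (ties broken toward
    the smallest theta, then the smallest t — conservative toward
    non-cancer), and computes lambda, the per-feature-normalized gain over
    theta = 0.  The sample is called cancer iff lambda > lambda_threshold.

    Raises :class:`InferenceError` when no selected feature has coverage.
    """
    if engine is None:
        engine = PanelLikelihood(panel, grid=grid or ThetaGrid(), min_coverage=min_coverage)
    if engine.thetas[0] != 0.0:
        raise ValueError("theta grid must include 0 as its first point")
    m, n = engine.align(profile)
    ll, K_used = engine.loglik_grid(m, n)
    if K_used == 0:
        raise InferenceError(
            f"sample {profile.sample_id}: no selected feature has coverage "
            f">= {engine.min_coverage}; refusing to predict"
        )
    ll0 = float(ll[0, 0])  # theta = 0 is class-independent
    # theta-major, class-minor flattening: first argmax = smallest theta, then t
    flat = ll.T.ravel()
    best = int(np.argmax(flat))
    best_ll = float(flat[best])
    q, ti = divmod(best, ll.shape[0])
    theta_hat = float(engine.thetas[q])
    t_hat: int | None = ti + 1
    lam = (best_ll - ll0) / K_used
    lam = max(lam, 0.0)
    if theta_hat == 0.0:
        t_hat = None
        lam = 0.0
    ties = [
        (float(engine.thetas[qq]), tt + 1)
        for qq in range(ll.shape[1])
        for tt in range(ll.shape[0])
        if abs(ll[tt, qq] - best_ll) <= 1e-9 and (qq, tt) != (q, ti)
    ]
    return InferenceResult(
        sample_id=profile.sample_id,
        theta_hat=theta_hat,
        t_hat=t_hat,
        lambda_score=lam,
        is_cancer=lam > lambda_threshold,
        used_features=K_used,
        loglik_grid=ll,
        thetas=engine.thetas.copy(),
        ties=ties,
    )


def predict_many(
    profiles: Sequence[SeqProfile],
    panel: ReferencePanel,
    grid: ThetaGrid | None = None,
    lambda_threshold: float = DEFAULT_LAMBDA_THRESHOLD,
    min_coverage: int = 1,
) -> list[InferenceResult]:
    """Run :func:`grid_mle` on many samples sharing one cached engine."""
    engine = PanelLikelihood(panel, grid=grid or ThetaGrid(), min_coverage=min_coverage)
    return [
        grid_mle(p, panel, lambda_threshold=lambda_threshold, engine=engine)
        for p in profiles
    ]
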