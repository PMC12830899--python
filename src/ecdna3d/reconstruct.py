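"""Consensus 3D structure inference from a normalized collapsed Hi-C matrix.

The model: the normalized contact count between collapsed bins ``i`` and
``j`` is Poisson with mean

    lambda_ij = beta * sum over copies a in R_i, b in R_j of d_ab**alpha,

where ``d_ab`` is the Euclidean distance between expanded bins in the sought
coordinate matrix ``X`` (Ne x 3), ``alpha < 0`` the power-law decay of
contacts with distance, and ``beta > 0`` a dataset scale.  The copy sums make
the likelihood duplication-aware: a collapsed count is explained jointly by
all copy pairs of its two bins.  The objective adds a spacing regularizer —
the variance of consecutive-bin distances — times a weight ``gamma``
(default ``0.05 * Ne``), expressing that the amplicon is a polymer chain
sampled at a fixed resolution.

Fitting alternates bounded L-BFGS steps over (alpha, beta) and over ``X``
(each axis constrained to [-1, 1]), started from a duplication-aware
metric-MDS embedding, with multiple random restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .cycles import BinMap
from .matrix import ContactMatrix
from .simulate import collapse_indicator

log = logging.getLogger(__name__)

D_FLOOR = 1e-6  # numerical floor on pairwise distances inside the optimizer


def circular_distance(a, b, ne: int):
    """Shortest bin separation on the circle: min(|a-b|, Ne - |a-b|).

    Indices are 0-based; works elementwise on arrays.
    """
    d = np.abs(np.asarray(a) - np.asarray(b))
    return np.minimum(d, ne - d)


def circular_distance_matrix(ne: int) -> np.ndarray:
    idx = np.arange(ne)
    return circular_distance(idx[:, None], idx[None, :], ne)


@dataclass
class Structure3D:
    """A fitted structure: coordinates plus model parameters and diagnostics."""

    coords: np.ndarray            # (Ne, 3), each axis within its bounds
    alpha: float
    beta: float
    gamma: float
    objective: float
    trace: list = field(default_factory=list)
    seed: int = 0
    converged: bool = False

    @property
    def ne(self) -> int:
        return self.coords.shape[0]


@dataclass
class FitConfig:
    n_restarts: int = 5
    max_rounds: int = 1000
    convergence_eps: float = 1e-4
    gamma: float | None = None          # None -> 0.05 * Ne
    axis_bounds: tuple = ((-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0))
    mode: str = "consensus"             # 'consensus' | 'ensemble'
    init: str = "mds"                   # 'mds' | 'random'
    fix_beta: float | None = None
    literal_regularizer: bool = False   # reproduce the printed (non-variance) form
    include_closing_edge: bool = False  # add the (Ne-1, 0) spacing to the chain
    x_step_maxiter: int = 50
    mds_maxiter: int = 300

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.convergence_eps <= 0:
            raise ValueError("convergence_eps must be positive")


class PoissonModel:
    """Precomputed index machinery for the duplication-aware Poisson objective."""

    def __init__(self, C: np.ndarray, binmap: BinMap, gamma: float,
                 literal_regularizer: bool = False,
                 include_closing_edge: bool = False):
        C = np.asarray(C, dtype=float)
        self.binmap = binmap
        self.ne = binmap.n_expanded
        self.nc = binmap.n_collapsed
        if C.shape != (self.nc, self.nc):
            raise ValueError("matrix shape does not match bin map")
        self.C = C
        self.gamma = gamma
        self.literal = literal_regularizer
        self.A = collapse_indicator(binmap)
        mult = np.asarray(binmap.multiplicities)
        # modeled pairs: upper triangle off-diagonal, plus diagonal entries of
        # duplicated bins (their distinct copies have well-defined distances)
        valid = np.triu(np.ones((self.nc, self.nc), dtype=bool), k=1)
        valid[np.diag_indices(self.nc)] = mult > 1
        self.valid = valid
        if include_closing_edge:
            self.chain = (np.arange(self.ne), np.r_[np.arange(1, self.ne), 0])
        else:
            self.chain = (np.arange(self.ne - 1), np.arange(1, self.ne))

    # -- likelihood pieces -------------------------------------------------

    def _distances(self, X: np.ndarray) -> np.ndarray:
        D = squareform(pdist(X))
        np.fill_diagonal(D, 1.0)       # self-distances never enter the model
        return np.maximum(D, D_FLOOR)

    def copy_sums(self, X: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """M_ij = sum of d_ab**alpha over copy pairs, and D for reuse."""
        D = self._distances(X)
        P = D**alpha
        np.fill_diagonal(P, 0.0)
        M = self.A @ P @ self.A.T
        return M, D

    def nll(self, M: np.ndarray, beta: float) -> float:
        lam = beta * M[self.valid]
        if np.any(lam <= 0):
            return np.inf
        c = self.C[self.valid]
        return float(np.sum(lam - c * np.log(lam)))

    def regularizer(self, X: np.ndarray) -> float:
        v = np.linalg.norm(X[self.chain[1]] - X[self.chain[0]], axis=1)
        n = len(v)
        if self.literal:
            return (np.sum(v**2) - np.sum(v) ** 2) / n
        return float(np.var(v))

    def objective(self, X: np.ndarray, alpha: float, beta: float) -> float:
        M, _ = self.copy_sums(X, alpha)
        return self.nll(M, beta) + self.gamma * self.regularizer(X)

    # -- gradients ---------------------------------------------------------

    def _dnll_dlambda(self, M: np.ndarray, beta: float) -> np.ndarray:
        """Symmetric matrix F with dNLL/dlambda entries (diagonal doubled:
        both copy orderings of a within-bin pair feed the same lambda_ii)."""
        lam = beta * M
        F = np.zeros_like(M)
        with np.errstate(divide="ignore", invalid="ignore"):
            G = 1.0 - self.C / lam
        F[self.valid] = G[self.valid]
        # F + F.T symmetrizes the strict upper triangle and doubles the
        # diagonal, which is exactly the double-counting of within-bin copy
        # pairs (both orderings feed lambda_ii)
        return F + F.T

    def grad_X(self, X: np.ndarray, alpha: float, beta: float) -> np.ndarray:
        M, D = self.copy_sums(X, alpha)
        F = self._dnll_dlambda(M, beta)
        Q = self.A.T @ F @ self.A        # per expanded pair dNLL/dlambda
        P1 = D ** (alpha - 1.0)
        np.fill_diagonal(P1, 0.0)
        S = Q * (beta * alpha * P1)      # dNLL/dd per ordered pair (a, b)
        K = S / D
        np.fill_diagonal(K, 0.0)
        grad = K.sum(axis=1)[:, None] * X - K @ X
        # spacing regularizer
        i, j = self.chain
        diff = X[j] - X[i]
        v = np.maximum(np.linalg.norm(diff, axis=1), D_FLOOR)
        n = len(v)
        if self.literal:
            dvar_dv = (2.0 * v - 2.0 * np.sum(v)) / n
        else:
            dvar_dv = 2.0 * (v - v.mean()) / n
        unit = diff / v[:, None]
        gi = self.gamma * dvar_dv[:, None] * unit
        np.add.at(grad, i, -gi)
        np.add.at(grad, j, gi)
        return grad

    def grad_alpha_beta(self, X: np.ndarray, alpha: float, beta: float) -> np.ndarray:
        D = self._distances(X)
        P = D**alpha
        np.fill_diagonal(P, 0.0)
        L = P * np.log(D)
        np.fill_diagonal(L, 0.0)
        M = self.A @ P @ self.A.T
        N = self.A @ L @ self.A.T
        lam = beta * M[self.valid]
        c = self.C[self.valid]
        g = 1.0 - c / lam
        dbeta = float(np.sum(g * M[self.valid]))
        dalpha = float(np.sum(g * beta * N[self.valid]))
        return np.array([dalpha, dbeta])

    def mle_beta(self, X: np.ndarray, alpha: float) -> float:
        """Closed-form beta maximizing the Poisson likelihood at fixed X, alpha."""
        M, _ = self.copy_sums(X, alpha)
        denom = float(M[self.valid].sum())
        return float(self.C[self.valid].sum() / denom) if denom > 0 else 1.0


# ---------------------------------------------------------------------------
# initialization


def init_redistribute(
    C: np.ndarray, binmap: BinMap, alpha0: float = -3.0
) -> tuple[np.ndarray, dict]:
    """Spread collapsed counts over copy pairs using circular distance as proxy.

    Off-diagonal counts are split in proportion to g_ab**alpha0 over the copy
    rectangle (so the copy sums reproduce the collapsed entries exactly);
    within-bin copy pairs are filled with the average normalized count of
    unique bin pairs at the same circular distance, falling back to the
    nearest circular distance that has unique pairs.
    """
    C = np.asarray(C, dtype=float)
    ne, nc = binmap.n_expanded, binmap.n_collapsed
    ci = np.asarray(binmap.collapsed_index)
    G = circular_distance_matrix(ne)
    W = np.where(G > 0, np.maximum(G, 1) ** float(alpha0), 0.0)
    # denominators: sum of weights over each copy rectangle
    A = collapse_indicator(binmap)
    denom = A @ W @ A.T                      # (nc, nc)
    E = np.zeros((ne, ne))
    off = ci[:, None] != ci[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        E[off] = (W[off] / denom[ci[:, None], ci[None, :]][off]) * C[ci[:, None], ci[None, :]][off]
    # averages over unique-unique pairs per circular distance, for Eq-7 fills
    mult = np.asarray(binmap.multiplicities)
    unique_bins = np.flatnonzero(mult[ci] == 1)
    fallback_used = False
    means: dict[int, float] = {}
    if len(unique_bins) >= 2:
        ug = G[np.ix_(unique_bins, unique_bins)]
        uc = C[np.ix_(ci[unique_bins], ci[unique_bins])]
        iu, ju = np.triu_indices(len(unique_bins), k=1)
        for g in np.unique(ug[iu, ju]):
            means[int(g)] = float(uc[iu, ju][ug[iu, ju] == g].mean())
    avail = np.array(sorted(means)) if means else np.array([])
    for i in range(nc):
        copies = binmap.copies[i]
        if len(copies) < 2:
            continue
        for x, a in enumerate(copies):
            for b in copies[x + 1:]:
                g = int(circular_distance(a, b, ne))
                if g in means:
                    val = means[g]
                elif len(avail):
                    g_near = int(avail[np.argmin(np.abs(avail - g))])
                    val = means[g_near]
                    fallback_used = True
                else:
                    val = float(C[np.triu_indices(nc, k=1)].mean())
                    fallback_used = True
                E[a, b] = E[b, a] = val
    if fallback_used:
        log.info("within-bin copy pairs used nearest-distance fallback averages")
    return E, {"alpha0": alpha0, "fallback_used": fallback_used}


def _mds_stress_and_grad(
    x: np.ndarray,
    ne: int,
    delta_idx: tuple[np.ndarray, np.ndarray],
    free_idx: tuple[np.ndarray, np.ndarray],
    fixed_delta: np.ndarray,
    beta0: float,
    cons_groups: list | None,
) -> tuple[float, np.ndarray]:
    """Joint stress over coordinates and (log of) free redistribution variables.

    Pairs listed in ``delta_idx`` have fixed wish distances ``fixed_delta``;
    pairs in ``free_idx`` carry free contact variables e (log-parameterized)
    with wish distance (e/beta0)**(-1/3), plus quadratic conservation
    penalties per collapsed pair in ``cons_groups`` (slices into the free
    vector with target counts).
    """
    X = x[: 3 * ne].reshape(ne, 3)
    loge = x[3 * ne:]
    e = np.exp(loge)
    grad = np.zeros_like(x)
    gX = grad[: 3 * ne].reshape(ne, 3)

    total = 0.0
    for (ii, jj), delta, free in (
        (delta_idx, fixed_delta, None),
        (free_idx, (e / beta0) ** (-1.0 / 3.0) if len(e) else np.empty(0), True),
    ):
        if len(ii) == 0:
            continue
        diff = X[ii] - X[jj]
        d = np.maximum(np.linalg.norm(diff, axis=1), D_FLOOR)
        ratio = d / delta - 1.0
        total += float(np.sum(ratio**2))
        coef = 2.0 * ratio / delta
        np.add.at(gX, ii, (coef / d)[:, None] * diff)
        np.add.at(gX, jj, -(coef / d)[:, None] * diff)
        if free:
            # dstress/dlog e = dstress/ddelta * ddelta/de * e ; ddelta/de = -delta/(3e)
            grad[3 * ne:] += 2.0 * ratio * (-d / delta**2) * (-delta / 3.0)
    if cons_groups:
        for sl, target, doubled in cons_groups:
            s = float(np.sum(e[sl]) * (2.0 if doubled else 1.0))
            total += (s - target) ** 2 / max(target, 1e-12)
            grad[3 * ne:][sl] += (
                2.0 * (s - target) / max(target, 1e-12) * (2.0 if doubled else 1.0) * e[sl]
            )
    return total, grad


def mds_initialize(
    C: np.ndarray,
    binmap: BinMap,
    seed: int = 0,
    maxiter: int = 300,
) -> np.ndarray:
    """Metric-MDS style initialization of the coordinates.

    Wish distances come from redistributing the normalized counts with a
    fixed decay exponent of -3 (the exponent used only for initialization);
    when duplication exists, the redistributed contacts of duplicated pairs
    are free variables penalized for violating the collapsed-sum constraint.
    Deterministic given ``seed``.
    """
    ne = binmap.n_expanded
    ci = np.asarray(binmap.collapsed_index)
    E0, _ = init_redistribute(C, binmap)
    # scale: beta0 from mean contact at unit circular distance
    G = circular_distance_matrix(ne)
    at1 = E0[G == 1]
    beta0 = float(at1[at1 > 0].mean()) if np.any(at1 > 0) else max(float(E0.max()), 1.0)

    iu, ju = np.triu_indices(ne, k=1)
    pos = E0[iu, ju] > 0
    iu, ju = iu[pos], ju[pos]
    mult = np.asarray(binmap.multiplicities)
    dup_pair = (mult[ci[iu]] > 1) | (mult[ci[ju]] > 1)

    fixed_i, fixed_j = iu[~dup_pair], ju[~dup_pair]
    free_i, free_j = iu[dup_pair], ju[dup_pair]
    fixed_delta = (E0[fixed_i, fixed_j] / beta0) ** (-1.0 / 3.0)

    cons_groups = []
    if len(free_i):
        # group free pairs by their collapsed pair to enforce conservation
        keys = np.minimum(ci[free_i], ci[free_j]) * binmap.n_collapsed + np.maximum(
            ci[free_i], ci[free_j]
        )
        order = np.argsort(keys, kind="stable")
        free_i, free_j = free_i[order], free_j[order]
        keys = keys[order]
        bounds = np.flatnonzero(np.r_[True, np.diff(keys) > 0])
        for s, t in zip(bounds, np.r_[bounds[1:], len(keys)]):
            i0, j0 = ci[free_i[s]], ci[free_j[s]]
            cons_groups.append((slice(s, t), float(C[i0, j0]), i0 == j0))

    rng = np.random.default_rng(seed)
    x0 = np.concatenate([
        rng.uniform(-1, 1, size=3 * ne),
        np.log(np.maximum(E0[free_i, free_j], 1e-8)),
    ])
    res = minimize(
        _mds_stress_and_grad,
        x0,
        args=(ne, (fixed_i, fixed_j), (free_i, free_j), fixed_delta, beta0, cons_groups),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    X = res.x[: 3 * ne].reshape(ne, 3)
    # bring the embedding into the feasible cube
    X = X - X.mean(axis=0)
    m = np.abs(X).max()
    if m > 1.0:
        X = X / m
    return X


# ---------------------------------------------------------------------------
# public objective / fitting


def objective(
    X: np.ndarray,
    alpha: float,
    beta: float,
    C: np.ndarray,
    binmap: BinMap,
    gamma: float = 0.0,
    literal_regularizer: bool = False,
) -> float:
    """Penalized negative Poisson log-likelihood (constant terms dropped).

    Sums lambda - C*ln(lambda) over unordered off-diagonal collapsed pairs
    (plus within-bin copy pairs of duplicated bins), with the consecutive-
    spacing variance times ``gamma`` added.  ``gamma=0`` recovers the pure
    likelihood term.
    """
    if alpha >= 0 or beta <= 0:
        raise ValueError("need alpha < 0 and beta > 0")
    D = squareform(pdist(np.asarray(X, dtype=float)))
    ci = np.asarray(binmap.collapsed_index)
    distinct = ci[:, None] != ci[None, :]
    same_loc_different_copy = (~distinct) & ~np.eye(binmap.n_expanded, dtype=bool)
    if np.any(D[distinct | same_loc_different_copy] == 0):
        raise ValueError("zero distance between modeled bins: lambda undefined")
    model = PoissonModel(C, binmap, gamma, literal_regularizer)
    return model.objective(np.asarray(X, dtype=float), alpha, beta)


def _alpha_beta_step(model: PoissonModel, X, alpha, beta, fix_beta):
    if fix_beta is not None:
        def f(a):
            M, _ = model.copy_sums(X, float(a[0]))
            return model.nll(M, fix_beta)
        res = minimize(f, [alpha], method="L-BFGS-B", bounds=[(-10.0, -1e-2)])
        return float(res.x[0]), fix_beta

    def f(p):
        a, b = float(p[0]), float(p[1])
        M, _ = model.copy_sums(X, a)
        val = model.nll(M, b)
        g = model.grad_alpha_beta(X, a, b) if np.isfinite(val) else np.zeros(2)
        return val, g

    res = minimize(f, [alpha, beta], jac=True, method="L-BFGS-B",
                   bounds=[(-10.0, -1e-2), (1e-6, None)])
    return float(res.x[0]), float(res.x[1])


def _x_step(model: PoissonModel, X, alpha, beta, bounds, maxiter):
    ne = model.ne
    lo = np.tile([b[0] for b in bounds], ne)
    hi = np.tile([b[1] for b in bounds], ne)

    def f(x):
        Xc = x.reshape(ne, 3)
        val = model.objective(Xc, alpha, beta)
        g = model.grad_X(Xc, alpha, beta).ravel() if np.isfinite(val) else np.zeros_like(x)
        return val, g

    res = minimize(f, np.clip(X.ravel(), lo, hi), jac=True, method="L-BFGS-B",
                   bounds=list(zip(lo, hi)), options={"maxiter": maxiter})
    return res.x.reshape(ne, 3)


def _single_fit(C, binmap, config: FitConfig, seed: int) -> Structure3D:
    ne = binmap.n_expanded
    gamma = config.gamma if config.gamma is not None else 0.05 * ne
    model = PoissonModel(C, binmap, gamma, config.literal_regularizer,
                         config.include_closing_edge)
    rng = np.random.default_rng(seed)
    if config.init == "mds":
        X = mds_initialize(C, binmap, seed=seed, maxiter=config.mds_maxiter)
    else:
        lo = np.array([b[0] for b in config.axis_bounds])
        hi = np.array([b[1] for b in config.axis_bounds])
        X = rng.uniform(lo, hi, size=(ne, 3))
    alpha = -3.0
    beta = config.fix_beta if config.fix_beta is not None else model.mle_beta(X, alpha)
    obj = model.objective(X, alpha, beta)
    objs = [obj]
    trace = [(0, obj, alpha, beta)]    # one structured record per round
    converged = False
    for rnd in range(1, config.max_rounds + 1):
        alpha_new, beta_new = _alpha_beta_step(model, X, alpha, beta, config.fix_beta)
        X_new = _x_step(model, X, alpha_new, beta_new, config.axis_bounds,
                        config.x_step_maxiter)
        obj_new = model.objective(X_new, alpha_new, beta_new)
        if not np.isfinite(obj_new) or obj_new > obj + 1e-9:
            break                      # reject non-improving round, keep best
        X, alpha, beta, obj = X_new, alpha_new, beta_new, obj_new
        objs.append(obj)
        trace.append((rnd, obj, alpha, beta))
        if len(objs) > 10:
            window = objs[-11:]
            rel = abs(window[-1] - window[0]) / max(np.abs(window).max(), 1e-12)
            if rel < config.convergence_eps:
                converged = True
                break
    return Structure3D(X, alpha, beta, gamma, obj, trace, seed, converged)


def fit_structure(
    C: np.ndarray | ContactMatrix,
    binmap: BinMap,
    config: FitConfig | None = None,
    seed: int = 0,
):
    """Fit the consensus structure (or an ensemble) by alternating optimization.

    Runs ``n_restarts`` independent initializations (restart seeds derived
    deterministically from ``seed``); each alternates a bounded quasi-Newton
    step over (alpha, beta) with one over the coordinates until the relative
    objective change over a 10-round window drops below ``convergence_eps``.
    Returns the best-objective :class:`Structure3D` in consensus mode, or the
    list of all restart results in ensemble mode.
    """
    if isinstance(C, ContactMatrix):
        C = C.values
    config = config or FitConfig()
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=config.n_restarts)
    results: list[Structure3D] = []
    for s in seeds:
        try:
            results.append(_single_fit(C, binmap, config, int(s)))
        except FloatingPointError:      # pragma: no cover - restart on blowup
            continue
    if not results:
        raise RuntimeError("all restarts failed")
    if config.mode == "ensemble":
        return results
    return min(results, key=lambda r: r.objective)


def flatness_test(
    C: np.ndarray | ContactMatrix,
    binmap: BinMap,
    beta_fixed: float,
    axis_limits=(1.0, 0.5, 0.25, 0.125),
    n_repeats: int = 5,
    seed: int = 0,
    config: FitConfig | None = None,
) -> dict[float, list[float]]:
    """Refit with the first axis squeezed to [-limit, limit]; collect objectives.

    With ``beta`` fixed, the structure cannot shrink isotropically to
    compensate, so a genuinely three-dimensional fold shows significantly
    worse likelihoods once the limit drops below its true extent, while a
    disk-like fold does not.  Each limit gets ``n_repeats`` random-restart
    fits; the objective samples per limit are returned for rank-sum testing.
    """
    if isinstance(C, ContactMatrix):
        C = C.values
    if beta_fixed <= 0:
        raise ValueError("beta_fixed must be positive")
    base = config or FitConfig(n_restarts=1, init="random", max_rounds=100)
    rng = np.random.default_rng(seed)
    out: dict[float, list[float]] = {}
    for limit in axis_limits:
        cfg = FitConfig(
            n_restarts=1,
            max_rounds=base.max_rounds,
            convergence_eps=base.convergence_eps,
            gamma=base.gamma,
            axis_bounds=((-limit, limit), (-1.0, 1.0), (-1.0, 1.0)),
            init="random",
            fix_beta=beta_fixed,
            x_step_maxiter=base.x_step_maxiter,
        )
        objs = [
            fit_structure(C, binmap, cfg, seed=int(rng.integers(0, 2**31 - 1))).objective
            for _ in range(n_repeats)
        ]
        out[float(limit)] = objs
    return out
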