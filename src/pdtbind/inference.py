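"""Parameter inference from multi-state perturbation-energy samples.

Three layers:

* UWHAM multistate reweighting — the unbinned weighted-histogram (MBAR)
  self-consistent equations on the reduced energies beta*W_k(u_sc_i),
  yielding per-state dimensionless free energies f_k and per-sample weights
  at the lam = 0 state.
* Weighted Gaussian kernel estimates of p0(u_sc) and of the lambda-function
  lam0(u_sc) = kB T d log p0/du_sc, used as graphical diagnostics and to
  initialize the analytical model.
* Maximum likelihood: the cost -sum_i log p_lam_i(u_sc_i | theta) where the
  per-state density follows from the potential-distribution relation with
  the soft-core change of variables; minimized over transformed parameters
  (simplex logits for weights, log for scales, logit for b).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, logit

from .analytic import (
    CollisionParams,
    CouplingModel,
    GaussianParams,
    ModelMode,
    p0_density,
)
from .pdt import QuadratureSpec, default_quadrature
from .samples import SampleSet, StateSamples
from .softcore import SchedulePoint, softcore_derivative, softcore_inverse, w_lambda
from .thermo import ThermoSpec, DEFAULT_THERMO

__all__ = [
    "ReweightingResult",
    "FitConfig",
    "FitResult",
    "uwham_weights",
    "uwham_stderr",
    "kernel_p0_estimate",
    "kernel_lambda_function",
    "negative_log_likelihood",
    "fit_model",
    "initialize_from_diagnostics",
]

_LOG_FLOOR = -690.0  # log of the smallest positive normal double, roughly


# ---------------------------------------------------------------------------
# UWHAM


@dataclass(frozen=True)
class ReweightingResult:
    """Converged multistate-reweighting solution.

    f holds the per-state dimensionless free energies anchored at f[0] = 0
    (state order follows the SampleSet); w0 are the normalized per-sample
    weights at the lam = 0 state, concatenated in sample order.
    """

    f: np.ndarray
    w0: np.ndarray
    ess: float
    n_iter: int
    converged: bool
    warnings: tuple[str, ...] = ()

    @property
    def log_w0(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.w0)


def _reduced_energies(samples: SampleSet, th: ThermoSpec) -> np.ndarray:
    """E[k, i] = beta * W_{lam_k}(u_sc_i) over pooled samples."""
    u = samples.all_u_sc()
    return np.stack([th.beta * np.asarray(w_lambda(u, st.point)) for st in samples.states])


def uwham_weights(
    samples: SampleSet,
    th: ThermoSpec = DEFAULT_THERMO,
    tol: float = 1e-8,
    max_iter: int = 50000,
    ess_floor: float = 20.0,
    f_start: np.ndarray | None = None,
) -> ReweightingResult:
    """Solve the UWHAM self-consistent equations.

    Converged when max |delta f| < tol between successive iterations.  A
    minimization of the convex UWHAM objective provides the starting point;
    self-consistent iteration then polishes to the stated tolerance.
    """
    samples = samples.drop_empty()
    if samples.n_states < 2:
        raise ValueError("UWHAM requires at least two states with samples")
    warn: list[str] = []
    energies = _reduced_energies(samples, th)  # (K, N)
    counts = samples.counts.astype(float)
    n_total = float(counts.sum())
    log_n = np.log(counts)

    def log_denom(f: np.ndarray) -> np.ndarray:
        # d_i = logsumexp_k [ log N_k + f_k - E_ki ]
        return logsumexp(log_n[:, None] + f[:, None] - energies, axis=0)

    if f_start is None:
        # convex objective: kappa(f) = mean_i d_i(f) - sum_k (N_k/N) f_k
        def objective(fr: np.ndarray):
            f = np.concatenate(([0.0], fr))
            d = log_denom(f)
            val = float(np.mean(d) - np.dot(counts / n_total, f))
            a = np.exp(log_n[:, None] + f[:, None] - energies - d[None, :])
            grad = a.sum(axis=1) / n_total - counts / n_total
            return val, grad[1:]

        res = minimize(objective, np.zeros(samples.n_states - 1), jac=True, method="L-BFGS-B")
        f = np.concatenate(([0.0], res.x))
    else:
        f = np.asarray(f_start, dtype=float).copy()

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = log_denom(f)
        f_new = -logsumexp(-energies - d[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"UWHAM did not converge within {max_iter} iterations")

    # weights at the lam = 0 target (W = 0 identically): log w0_i = -d_i
    d = log_denom(f)
    log_w0 = -d - logsumexp(-d)
    w0 = np.exp(log_w0)
    ess = float(1.0 / np.sum(w0**2))
    if ess < ess_floor:
        warn.append(
            f"effective sample size at lam=0 is {ess:.1f} (< {ess_floor}); "
            "states may not overlap the decoupled state"
        )
    return ReweightingResult(
        f=f, w0=w0, ess=ess, n_iter=it, converged=converged, warnings=tuple(warn)
    )


def uwham_stderr(
    samples: SampleSet,
    th: ThermoSpec = DEFAULT_THERMO,
    n_boot: int = 20,
    seed: int = 0,
    result: ReweightingResult | None = None,
) -> np.ndarray:
    """Bootstrap standard errors of the UWHAM free energies f_k.

    Resamples within each state (samples are treated as independent) and
    re-solves warm-started from the full-data solution.
    """
    if result is None:
        result = uwham_weights(samples, th)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        states = [
            StateSamples(st.state_index, st.point, rng.choice(st.u_sc, size=st.n, replace=True))
            for st in samples.states
        ]
        boot = SampleSet(states, samples.softcore)
        reps.append(uwham_weights(boot, th, f_start=result.f.copy()).f)
    return np.std(np.asarray(reps), axis=0, ddof=1)


# ---------------------------------------------------------------------------
# kernel diagnostics


def kernel_p0_estimate(
    samples: SampleSet,
    weights: ReweightingResult,
    bandwidth: float = 1.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Gaussian kernel estimate of p0(u_sc) on a grid.

    Returns (grid, density); the density is an exact mixture of normals and
    integrates to 1 over the real line.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    u = samples.all_u_sc()
    if grid is None:
        grid = np.linspace(u.min() - 4 * bandwidth, u.max() + 4 * bandwidth, 801)
    dens = _weighted_kde(grid, u, weights.w0, bandwidth)[0]
    return grid, dens


def kernel_lambda_function(
    samples: SampleSet,
    weights: ReweightingResult,
    bandwidth: float = 1.0,
    grid: np.ndarray | None = None,
    th: ThermoSpec = DEFAULT_THERMO,
    density_floor: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel estimate of lam0(u_sc) = kB T d log p0 / du_sc.

    Values where the density estimate falls below density_floor (relative to
    its maximum) are masked as NaN rather than raising.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    u = samples.all_u_sc()
    if grid is None:
        grid = np.linspace(u.min() - 4 * bandwidth, u.max() + 4 * bandwidth, 801)
    dens, ddens = _weighted_kde(grid, u, weights.w0, bandwidth)
    lam = np.full_like(dens, np.nan)
    ok = dens > density_floor * np.max(dens)
    lam[ok] = th.kt * ddens[ok] / dens[ok]
    return grid, lam


def _weighted_kde(
    grid: np.ndarray, u: np.ndarray, w: np.ndarray, h: float, chunk: int = 20000
) -> tuple[np.ndarray, np.ndarray]:
    """Return (sum_i w_i N_h(g - u_i), its derivative w.r.t. g)."""
    dens = np.zeros_like(grid)
    ddens = np.zeros_like(grid)
    norm = 1.0 / (h * np.sqrt(2.0 * np.pi))
    for start in range(0, u.size, chunk):
        ui = u[start : start + chunk]
        wi = w[start : start + chunk]
        z = (grid[:, None] - ui[None, :]) / h
        k = np.exp(-0.5 * z * z)
        dens += norm * (k @ wi)
        ddens += norm * ((k * (-z / h)) @ wi)
    return dens, ddens


# ---------------------------------------------------------------------------
# maximum likelihood


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings for the maximum-likelihood fit."""

    vary_collision: bool = True
    optimizer: str = "L-BFGS-B"
    max_iter: int = 500
    cost_tol: float = 1e-9
    param_tol: float = 1e-6
    nodes: int = 19           # Gauss-Hermite nodes for the mode convolutions
    quad_nodes: int = 2001    # u_sc grid for the K(lambda) normalizers
    interpolate: bool = True  # grid-interpolated sample log-densities
    multi_start: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nodes < 5:
            raise ValueError("nodes must be >= 5")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_model`."""

    model: CouplingModel
    cost: float
    cost_initial: float
    n_iter: int
    converged: bool
    message: str
    config: FitConfig

    def to_dict(self) -> dict:
        return {
            "cost": self.cost,
            "cost_initial": self.cost_initial,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "message": self.message,
            "seed": self.config.seed,
            "parameters": [
                {
                    "weight": m.weight,
                    "b": m.collision.b_no_collision,
                    "u0bar": m.gaussian.mean_u0,
                    "sigma": m.gaussian.sigma,
                    "epsilon": m.collision.epsilon,
                    "u_tilde": m.collision.u_tilde,
                    "n_l": m.collision.n_l,
                }
                for m in self.model.modes
            ],
        }


class _LikelihoodData:
    """Theta-independent precomputations for the multi-state likelihood."""

    def __init__(
        self,
        samples: SampleSet,
        th: ThermoSpec,
        quad_nodes: int,
        grid_lower: float,
    ):
        samples = samples.drop_empty()
        sc = samples.softcore
        self.th = th
        self.sc = sc
        upper = sc.u_max - 1e-6 * (sc.u_max - sc.u_cut)
        self.grid = np.linspace(grid_lower, upper, quad_nodes)
        self.grid_u = softcore_inverse(self.grid, sc)
        with np.errstate(over="ignore"):
            gd = softcore_derivative(self.grid_u, sc)
        self.grid_log_jac = -np.log(np.maximum(gd, 1e-300))
        # per-state -beta W on the grid and on that state's samples
        self.state_bw_grid = [
            th.beta * np.asarray(w_lambda(self.grid, st.point)) for st in samples.states
        ]
        self.samples_usc = [st.u_sc for st in samples.states]
        self.samples_u = [softcore_inverse(st.u_sc, sc) for st in samples.states]
        self.samples_bw = [
            th.beta * np.asarray(w_lambda(st.u_sc, st.point)) for st in samples.states
        ]
        self.samples_log_jac = [
            -np.log(np.maximum(softcore_derivative(u, sc), 1e-300)) for u in self.samples_u
        ]
        self.n_total = samples.n_total
        self.pooled_u = np.concatenate(self.samples_u)
        self.pooled_usc = np.concatenate(self.samples_usc)
        self.splits = np.cumsum([u.size for u in self.samples_u])[:-1]

    def nll(self, model: CouplingModel, nodes: int, interpolate: bool = False) -> float:
        """Multi-state cost.  With ``interpolate`` the sample log-densities are
        linearly interpolated from the quadrature grid (the density is smooth
        in u_sc), which makes the cost nearly independent of sample count."""
        with np.errstate(over="ignore", under="ignore"):
            grid_p0 = np.asarray(p0_density(self.grid_u, model, nodes=nodes))
        log_grid = np.where(
            grid_p0 > 0, np.log(np.maximum(grid_p0, 1e-300)), _LOG_FLOOR
        ) + self.grid_log_jac
        if interpolate:
            log_pooled_sc = np.interp(self.pooled_usc, self.grid, log_grid)
            per_state = np.split(log_pooled_sc, self.splits)
        else:
            with np.errstate(over="ignore", under="ignore"):
                pooled_p0 = np.asarray(p0_density(self.pooled_u, model, nodes=nodes))
            log_pooled = np.where(
                pooled_p0 > 0, np.log(np.maximum(pooled_p0, 1e-300)), _LOG_FLOOR
            )
            per_state = [
                lp + lj
                for lp, lj in zip(np.split(log_pooled, self.splits), self.samples_log_jac)
            ]
        total = 0.0
        for k, lp in enumerate(per_state):
            log_int = log_grid - self.state_bw_grid[k]
            m = np.max(log_int)
            log_k = m + np.log(np.trapezoid(np.exp(log_int - m), self.grid))
            terms = lp - self.samples_bw[k] - log_k
            total -= float(np.sum(np.maximum(terms, _LOG_FLOOR)))
        return total


def negative_log_likelihood(
    model: CouplingModel,
    samples: SampleSet,
    th: ThermoSpec = DEFAULT_THERMO,
    nodes: int = 19,
    quad_nodes: int = 2001,
) -> float:
    """-log L(theta) = -sum_i log p_{lam_i}(u_sc_i | theta).

    The per-state density is exp(-beta W_lam) p0(u_sc) / K(lam) with the
    soft-core Jacobian; samples with vanishing model density contribute a
    large finite penalty instead of an infinite cost.
    """
    lower = min(model.support_lower(12.0), samples.softcore.u_cut - 1.0,
                float(np.min(samples.all_u_sc())) - 5.0)
    data = _LikelihoodData(samples, th, quad_nodes, lower)
    return data.nll(model, nodes)


# --- parameter transforms ---------------------------------------------------


class _Packing:
    """Bijection between a CouplingModel and an unconstrained vector."""

    def __init__(self, template: CouplingModel, vary_collision: bool):
        self.m = template.n_modes
        self.all_gaussian = all(
            mm.collision.b_no_collision == 1.0 for mm in template.modes
        )
        self.vary_collision = vary_collision and not self.all_gaussian
        self.template = template

    def pack(self, model: CouplingModel) -> np.ndarray:
        v: list[float] = []
        if self.m > 1:
            w = np.log(np.maximum(model.weights, 1e-300))
            v.extend(w[1:] - w[0])
        for mm in model.modes:
            v.append(mm.gaussian.mean_u0)
            v.append(np.log(mm.gaussian.sigma))
            if self.vary_collision:
                c = mm.collision
                b = np.clip(c.b_no_collision, 1e-12, 1.0 - 1e-12)
                v.append(logit(b))
                v.append(np.log(c.epsilon))
                v.append(np.log(max(c.u_tilde, 1e-4)))
                v.append(np.log(max(c.n_l - 1.0, 1e-4)))
        return np.array(v)

    def unpack(self, v: np.ndarray) -> CouplingModel:
        i = 0
        if self.m > 1:
            logits = np.concatenate(([0.0], v[: self.m - 1]))
            w = np.exp(logits - logsumexp(logits))
            i = self.m - 1
        else:
            w = np.array([1.0])
        modes = []
        for k in range(self.m):
            u0 = v[i]
            sig = float(np.exp(np.clip(v[i + 1], -20, 20)))
            i += 2
            tpl = self.template.modes[k].collision
            if self.vary_collision:
                b = float(expit(v[i]))
                eps = float(np.exp(np.clip(v[i + 1], -20, 20)))
                ut = float(np.exp(np.clip(v[i + 2], -25, 25)))
                nl = 1.0 + float(np.exp(np.clip(v[i + 3], -25, 25)))
                i += 4
                coll = CollisionParams(b, eps, ut, nl)
            else:
                coll = tpl
            modes.append(
                ModelMode(float(w[k]), GaussianParams(float(u0), sig), coll)
            )
        return CouplingModel(modes, label=self.template.label)


def fit_model(
    initial: CouplingModel,
    samples: SampleSet,
    th: ThermoSpec = DEFAULT_THERMO,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Refine the analytical model by minimizing the multi-state likelihood cost.

    Returns the best parameters found; the final cost never exceeds the
    initial cost (the initial model is kept if the optimizer fails to
    improve on it).
    """
    cfg = cfg or FitConfig()
    samples = samples.drop_empty()
    lower = min(initial.support_lower(12.0), samples.softcore.u_cut - 1.0,
                float(np.min(samples.all_u_sc())) - 5.0)
    data = _LikelihoodData(samples, th, cfg.quad_nodes, lower)
    packing = _Packing(initial, cfg.vary_collision)

    def cost(v: np.ndarray) -> float:
        try:
            model = packing.unpack(v)
        except (ValueError, FloatingPointError):
            return 1e12
        val = data.nll(model, cfg.nodes, interpolate=cfg.interpolate)
        return val if np.isfinite(val) else 1e12

    x0 = packing.pack(initial)
    cost0 = cost(x0)
    starts = [x0]
    if cfg.multi_start > 0:
        rng = np.random.default_rng(cfg.seed)
        starts += [x0 + rng.normal(scale=0.25, size=x0.size) for _ in range(cfg.multi_start)]

    best_x, best_cost, best_res = x0, cost0, None
    for s in starts:
        res = minimize(
            cost,
            s,
            method=cfg.optimizer,
            options={"maxiter": cfg.max_iter, "ftol": cfg.cost_tol, "gtol": 1e-7}
            if cfg.optimizer == "L-BFGS-B"
            else {"maxiter": cfg.max_iter},
        )
        if res.fun < best_cost:
            best_x, best_cost, best_res = res.x, float(res.fun), res
    converged = best_res is not None and bool(best_res.success)
    if best_res is None:
        message = "optimizer did not improve on the initial parameters"
    else:
        message = str(best_res.message)
    return FitResult(
        model=packing.unpack(best_x),
        cost=min(best_cost, cost0),
        cost_initial=cost0,
        n_iter=int(getattr(best_res, "nit", 0)) if best_res is not None else 0,
        converged=converged,
        message=message,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# diagnostics-based initialization


def initialize_from_diagnostics(
    samples: SampleSet,
    weights: ReweightingResult | None = None,
    bandwidth: float = 1.0,
    mode_count: int = 1,
    th: ThermoSpec = DEFAULT_THERMO,
    size_hint: float = 3.0,
) -> CouplingModel:
    """Heuristic initial model from reweighting diagnostics.

    The most-coupled state carries clash-free, linear-response (Gaussian)
    samples: its distribution is the decoupled-ensemble Gaussian core tilted
    to mean u0 - lam beta sigma^2 at unchanged width.  The initializer
    clusters that state's samples into ``mode_count`` groups, reads each
    group's mean and standard deviation, back-shifts the means by
    lam beta sigma^2, assigns decoupled weights from the UWHAM lam = 0
    responsibilities of the clusters, estimates b from the kernel-density
    mass inside each Gaussian core, and fills in order-of-magnitude
    collisional defaults (epsilon = 1 kcal/mol, u_tilde = 1 kcal/mol,
    n_l = size_hint).  With mode_count = 1 on clearly bimodal data the
    dominant (heavier) component's parameters are returned.
    """
    if mode_count < 1:
        raise ValueError("mode_count must be >= 1")
    if samples.n_total < 100:
        raise ValueError("too few samples for diagnostics-based initialization")
    samples = samples.drop_empty()
    if weights is None:
        weights = uwham_weights(samples, th)

    top = max(samples.states, key=lambda st: st.point.lam)
    lam_eff = top.point.lam2 if top.point.lam1 == top.point.lam2 else top.point.lam
    u_top = np.sort(top.u_sc)

    def cluster(k: int) -> list[np.ndarray]:
        # 1-d k-means seeded at evenly spaced quantiles
        centers = np.quantile(u_top, (np.arange(k) + 0.5) / k)
        for _ in range(50):
            assign = np.abs(u_top[:, None] - centers[None, :]).argmin(axis=1)
            new = np.array(
                [u_top[assign == j].mean() if np.any(assign == j) else centers[j]
                 for j in range(k)]
            )
            if np.allclose(new, centers):
                break
            centers = new
        return [u_top[assign == j] for j in range(k)]

    groups = cluster(mode_count)
    if mode_count == 1:
        # keep only the dominant component when the coupled state is bimodal
        two = cluster(2)
        if all(g.size > 10 for g in two):
            m0, m1 = two[0].mean(), two[1].mean()
            s_pool = np.sqrt(0.5 * (two[0].var() + two[1].var()))
            # a k=2 split of a single Gaussian yields |dm|/s_within ~ 2.7;
            # genuinely separated modes give >= ~3.2
            if abs(m1 - m0) > 3.2 * max(s_pool, 1e-6):
                groups = [max(two, key=lambda g: g.size)]
    groups = [g if g.size >= 2 else u_top for g in groups]

    grid, dens = kernel_p0_estimate(samples, weights, bandwidth)
    pooled = samples.all_u_sc()
    centers = np.array([g.mean() for g in groups])

    # decoupled weights: UWHAM lam=0 mass of pooled samples nearest each core
    if len(groups) > 1:
        assign = np.abs(pooled[:, None] - centers[None, :]).argmin(axis=1)
        raw_w = np.array(
            [max(float(weights.w0[assign == k].sum()), 1e-6) for k in range(len(groups))]
        )
    else:
        raw_w = np.array([1.0])
    w = raw_w / raw_w.sum()

    modes = []
    for g in groups:
        sigma = float(max(g.std(ddof=1), 0.3))
        mu = float(g.mean() + lam_eff * th.beta * sigma**2)
        core = (grid >= mu - 4 * sigma) & (grid <= mu + 2 * sigma)
        b = float(np.clip(np.trapezoid(np.where(core, dens, 0.0), grid), 1e-8, 1.0))
        modes.append((mu, sigma, b))
    return CouplingModel(
        [
            ModelMode(
                weight=float(wk),
                gaussian=GaussianParams(mu, sigma),
                collision=CollisionParams(b, 1.0, 1.0, max(size_hint, 1.0)),
            )
            for wk, (mu, sigma, b) in zip(w, modes)
        ],
        label="diagnostics initializer",
    )
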