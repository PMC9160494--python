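"""Flexible parametric survival model on the log cumulative-hazard scale.

With age ``t`` as the timescale and ``x = ln t``, the model for exposure
category ``c`` with covariates ``z`` is

    ln H(t; c, z) = s_c(x; gamma_c) + beta' z,

where ``s_c`` is a restricted cubic spline of log age.  The hazard follows as
``h(t) = H(t) * s_c'(x) / t``.  Subjects enter the risk set at their baseline
age (left truncation): the log likelihood is

    sum_i  d_i * ln h(t_i)  -  [ H(t_i) - H(t0_i) ],

with ``t0`` the entry age and ``d`` the event indicator.  Two parameterisations
are supported: a separate spline baseline per category (the default, used for
disease-free-years estimation) and a single shared baseline with categories as
proportional covariates (used for hazard ratios).

Maximisation is quasi-Newton (BFGS with analytic gradient) on an
orthogonalised basis, started from a Nelson-Aalen regression and from a
projection of the previous (fewer-knot) fit; a damped-Newton polish handles
stalled line searches.  Hazard positivity enters through a smooth softplus
barrier on the spline slope at event times — exact wherever the hazard is
healthy — and every accepted fit is re-validated: the predicted cumulative
hazard must be non-decreasing (log-log slope >= 0.1) and plausibly scaled
over the observed age range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .splines import KnotSet, place_knots, rcs_design, rcs_deriv

_PENALTY = 1e10
_BARRIER_SHARPNESS = 100.0  # softplus sharpness for the slope-positivity barrier

PROPORTIONAL = "__baseline__"  # knot/gamma key of the shared-baseline variant


def _soft_log_slope(slope: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log(softplus(slope)) and its derivative, numerically stable.

    softplus_k(s) = log(1 + exp(k s)) / k equals s to within exp(-k s)/k, so
    for the slopes an accepted fit exhibits (>= 0.1 on the validation grid)
    the barrier is exact to ~1e-7; it only differs where the likelihood is
    invalid anyway.
    """
    z = np.clip(_BARRIER_SHARPNESS * slope, -500.0, None)
    sp = np.logaddexp(0.0, z) / _BARRIER_SHARPNESS
    sp = np.maximum(sp, 1e-300)
    with np.errstate(divide="ignore"):
        lnsp = np.where(z > 30.0, np.log(np.maximum(slope, 1e-300)), np.log(sp))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))
    dlnsp = np.where(z > 30.0, 1.0 / np.maximum(slope, 1e-300), sig / sp)
    return lnsp, dlnsp


class ConvergenceError(RuntimeError):
    """Raised when the optimiser fails after bounded restarts; carries the trace."""


@dataclass(frozen=True)
class ModelConfig:
    """Fitting options.

    ``knot_candidates`` are internal-knot counts tried when ``selection`` is
    ``"aic"``; with ``selection="fixed"`` the first candidate is used as-is.
    ``baseline`` chooses between per-category splines and the proportional
    (shared-baseline) variant used for hazard ratios.
    """

    category_column: str = "cat6"
    event_column: str = "event"
    entry_column: str = "entry_age"
    exit_column: str = "exit_age"
    knot_candidates: tuple[int, ...] = (0, 1, 2, 3, 4)
    selection: str = "aic"  # "aic" | "fixed"
    covariate_columns: tuple[str, ...] = ()
    baseline: str = "per_category"  # "per_category" | "proportional"
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if not self.knot_candidates:
            raise ValueError("knot_candidates must be non-empty")
        if self.selection not in ("aic", "fixed"):
            raise ValueError("selection must be 'aic' or 'fixed'")
        if self.baseline not in ("per_category", "proportional"):
            raise ValueError("baseline must be 'per_category' or 'proportional'")


@dataclass
class CHModelFit:
    """A fitted cumulative-hazard-scale model."""

    categories: tuple[str, ...]
    knots: dict[str, KnotSet]
    gamma: dict[str, np.ndarray]  # coefficients on the standardised basis
    beta: np.ndarray
    covariate_names: tuple[str, ...]
    loglik: float
    n_params: int
    n_subjects: int
    converged: bool
    message: str = ""
    cov: np.ndarray | None = None  # parameter covariance, packed order
    param_names: tuple[str, ...] = ()
    baseline: str = "per_category"
    config: ModelConfig | None = None
    # per-key linear map T with standardised design = raw design @ T;
    # fitted once from the data and reused for every prediction
    basis_transform: dict[str, np.ndarray] | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def raw_gamma(self, key: str) -> np.ndarray:
        """Spline coefficients on the raw (unstandardised) basis."""
        return self._transform(key) @ self.gamma[key]

    def _transform(self, key: str) -> np.ndarray:
        if self.basis_transform is None or key not in self.basis_transform:
            return np.eye(self.knots[key].n_basis)
        return self.basis_transform[key]

    def spline_eta(self, category: str, ages) -> np.ndarray:
        key = PROPORTIONAL if self.baseline == "proportional" else category
        x = np.log(np.atleast_1d(np.asarray(ages, dtype=float)))
        eta = rcs_design(x, self.knots[key]) @ self._transform(key) @ self.gamma[key]
        if self.baseline == "proportional" and category is not None:
            name = f"cat:{category}"
            if name in self.covariate_names:
                eta = eta + self.beta[self.covariate_names.index(name)]
        return eta

    def spline_slope(self, category: str, ages) -> np.ndarray:
        key = PROPORTIONAL if self.baseline == "proportional" else category
        x = np.log(np.atleast_1d(np.asarray(ages, dtype=float)))
        return rcs_deriv(x, self.knots[key]) @ self._transform(key) @ self.gamma[key]


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


class CHLikelihood:
    """Packed log likelihood with analytic gradient.

    Parameters pack as ``[gamma_block(cat) for cat in categories] + [beta]``;
    the proportional variant has a single gamma block.  Design matrices are
    precomputed once per dataset, so repeated evaluation (optimiser,
    bootstrap warm starts) is a handful of BLAS calls.
    """

    def __init__(
        self,
        entry: np.ndarray,
        exit_: np.ndarray,
        event: np.ndarray,
        cat_codes: np.ndarray,
        categories: tuple[str, ...],
        knots: dict[str, KnotSet],
        Z: np.ndarray | None = None,
        shared_baseline: bool = False,
        transforms: dict[str, np.ndarray] | None = None,
    ):
        if np.any(exit_ < entry):
            raise ValueError("every subject needs entry_age <= exit_age")
        if np.any(entry <= 0):
            raise ValueError("ages must be positive (age timescale)")
        self.categories = categories
        self.shared = shared_baseline
        self.keys = (PROPORTIONAL,) if shared_baseline else categories
        self.knots = knots
        self.Z = Z
        self.n = len(exit_)
        self.n_beta = 0 if Z is None else Z.shape[1]
        self.transforms = {}
        self.blocks = []  # per key: (rows, d, lx, B, B0, Bp, Zrows)
        x, x0 = np.log(exit_), np.log(entry)
        for ki, key in enumerate(self.keys):
            rows = np.arange(self.n) if shared_baseline else np.flatnonzero(cat_codes == ki)
            ks = knots[key]
            B = rcs_design(x[rows], ks)
            if transforms is not None and key in transforms:
                T = transforms[key]
            else:
                # orthonormalise the design once per fit: the raw cubic basis on
                # a narrow log-age span is nearly collinear and cripples BFGS
                T = _standardising_transform(B)
            self.transforms[key] = T
            self.blocks.append(
                (
                    rows,
                    event[rows].astype(float),
                    x[rows],
                    B @ T,
                    rcs_design(x0[rows], ks) @ T,
                    rcs_deriv(x[rows], ks) @ T,
                    None if Z is None else Z[rows],
                )
            )
        self.block_sizes = [knots[k].n_basis for k in self.keys]
        self.n_params = sum(self.block_sizes) + self.n_beta

    def unpack(self, theta: np.ndarray):
        gammas, ofs = [], 0
        for size in self.block_sizes:
            gammas.append(theta[ofs : ofs + size])
            ofs += size
        return gammas, theta[ofs:]

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        gammas, beta = self.unpack(theta)
        ll = 0.0
        grad = np.zeros_like(theta)
        ofs = 0
        gbeta = np.zeros(self.n_beta)
        for (rows, d, lx, B, B0, Bp, Zr), g, size in zip(
            self.blocks, gammas, self.block_sizes
        ):
            slope = Bp @ g
            ev = d > 0
            # ln(slope) at event times through a softplus barrier: exact for
            # healthy slopes, smooth (finite, differentiable) when an iterate
            # strays into slope <= 0, so line searches never hit a cliff.
            # Accepted fits are re-validated against the exact likelihood.
            lnsp, dlnsp = _soft_log_slope(slope)
            eta = B @ g
            eta0 = B0 @ g
            if Zr is not None and self.n_beta:
                zb = Zr @ beta
                eta = eta + zb
                eta0 = eta0 + zb
            # clip keeps stray iterates finite; the optimum is far below this
            H = np.exp(np.clip(eta, -745.0, 300.0))
            H0 = np.exp(np.clip(eta0, -745.0, 300.0))
            ll += float(np.sum(d * (eta + lnsp - lx)) - np.sum(H - H0))
            w = d - H + H0
            gblock = B.T @ (d - H) + B0.T @ H0
            gblock += Bp.T @ (d * dlnsp)
            grad[ofs : ofs + size] += gblock
            if Zr is not None and self.n_beta:
                gbeta += Zr.T @ w
            ofs += size
        if self.n_beta:
            grad[-self.n_beta :] = gbeta
        if not np.isfinite(ll) or ll > 1e6:
            # a decreasing H over censored follow-up masquerades as reward;
            # steer smoothly back toward the origin instead of cliff-edging
            pen = _PENALTY + 1e3 * float(theta @ theta)
            return -pen, -2e3 * theta
        return ll, grad

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        v, g = self.value_and_grad(theta)
        return -v, -g

    def valid(self, theta: np.ndarray) -> bool:
        """True when the hazard is positive at every event time."""
        gammas, _ = self.unpack(theta)
        for (rows, d, lx, B, B0, Bp, Zr), g in zip(self.blocks, gammas):
            if np.any((Bp @ g)[d > 0] <= 0):
                return False
        return True

    def newton(self, theta0: np.ndarray, tol: float = 1e-8, maxiter: int = 40):
        """Damped Newton with the analytic Hessian; block-separable case only.

        Valid when there are no shared covariates (the likelihood then splits
        by category).  Converges in a couple of iterations from a warm start,
        which is what makes thousand-replicate bootstraps cheap.  Returns the
        packed optimum and log likelihood, or None when a safeguarded step
        fails (callers fall back to BFGS).
        """
        if self.n_beta:
            return None
        gammas, _ = self.unpack(theta0)
        out, total_ll = [], 0.0
        for (rows, d, lx, B, B0, Bp, _), g0 in zip(self.blocks, gammas):
            ev = d > 0

            def vgh(g):
                slope = Bp @ g
                if np.any(slope[ev] <= 0):
                    return None
                eta, eta0 = B @ g, B0 @ g
                H = np.exp(np.clip(eta, -745.0, 300.0))
                H0 = np.exp(np.clip(eta0, -745.0, 300.0))
                dslope = np.where(ev, d / np.where(ev, slope, 1.0), 0.0)
                ll = float(np.sum(d * (eta + np.log(np.where(ev, slope, 1.0)) - lx))
                           - np.sum(H - H0))
                if not np.isfinite(ll) or ll > 1e6:
                    return None
                grad = B.T @ (d - H) + B0.T @ H0 + Bp.T @ dslope
                hess = -(B.T * H) @ B + (B0.T * H0) @ B0 - (Bp.T * (dslope / np.where(ev, slope, 1.0))) @ Bp
                return ll, grad, hess

            g = np.asarray(g0, dtype=float).copy()
            cur = vgh(g)
            if cur is None:
                return None
            ll, grad, hess = cur
            for _ in range(maxiter):
                if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
                    break
                try:
                    step = np.linalg.solve(hess, -grad)
                except np.linalg.LinAlgError:
                    return None
                t, new = 1.0, None
                for _ in range(25):
                    new = vgh(g + t * step)
                    if new is not None and new[0] >= ll - 1e-9:
                        break
                    t *= 0.5
                else:
                    return None
                g = g + t * step
                ll, grad, hess = new
            else:
                return None
            out.append(g)
            total_ll += ll
        return np.concatenate(out), total_ll


def _standardising_transform(B: np.ndarray) -> np.ndarray:
    """Map T with B @ T orthonormal (up to sqrt(n)); identity on failure."""
    p = B.shape[1]
    if B.shape[0] <= p:
        return np.eye(p)
    R = np.linalg.qr(B, mode="r")
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        return np.eye(p)
    T = np.linalg.inv(R) * np.sqrt(B.shape[0])
    return T if np.all(np.isfinite(T)) else np.eye(p)


def _weibull_start(entry, exit_, event) -> np.ndarray:
    """Exponential-rate starting values: ln H = ln(a) + 1 * ln t."""
    risk = float(np.sum(exit_ - entry))
    d = max(float(np.sum(event)), 0.5)
    a = d / max(risk, 1e-12)
    return np.array([np.log(a), 1.0])


def _nelson_aalen_start(entry, exit_, event, knots: KnotSet) -> np.ndarray | None:
    """Initial gamma from regressing the log Nelson-Aalen estimate on the basis.

    The Nelson-Aalen cumulative hazard (risk sets honouring delayed entry)
    pins the coefficients near the truth, keeping the optimiser away from the
    flat ridge where a huge cumulative-hazard level with a near-zero spline
    slope mimics a plausible hazard inside the observed age range.
    """
    ev_times = np.sort(exit_[event == 1])
    if len(np.unique(ev_times)) < knots.n_basis:
        return None
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    times, counts = np.unique(ev_times, return_counts=True)
    n_at = (np.searchsorted(entry_sorted, times, side="left")
            - np.searchsorted(exit_sorted, times, side="left"))
    n_at = np.maximum(n_at, 1)
    # the Nelson-Aalen curve starts at the earliest entry age; add a crude
    # constant-rate level for the unobserved hazard before it, otherwise the
    # start (and with it the optimiser) drifts onto the weakly identified
    # shifted-level ridge
    rate = float(np.sum(event)) / max(float(np.sum(exit_ - entry)), 1e-12)
    H = np.cumsum(counts / n_at) + rate * float(entry_sorted[0])
    coef, *_ = np.linalg.lstsq(rcs_design(np.log(times), knots), np.log(H), rcond=None)
    return coef


def _project_start(prev_fit_eta, x_grid, knots: KnotSet) -> np.ndarray:
    """Least-squares projection of a fitted log-cumulative-hazard curve onto a
    new basis; warm-starts higher-knot fits near the previous optimum."""
    B = rcs_design(x_grid, knots)
    coef, *_ = np.linalg.lstsq(B, prev_fit_eta, rcond=None)
    return coef


def _hessian(nll, theta: np.ndarray, grad_fn) -> np.ndarray:
    """Observed information by central differences of the analytic gradient."""
    p = len(theta)
    Hm = np.zeros((p, p))
    for j in range(p):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        Hm[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * h)
    return 0.5 * (Hm + Hm.T)


def _extract(df: pd.DataFrame, config: ModelConfig):
    entry = df[config.entry_column].to_numpy(float)
    exit_ = df[config.exit_column].to_numpy(float)
    event = df[config.event_column].to_numpy()
    cats = tuple(sorted(df[config.category_column].astype(str).unique()))
    codes = pd.Categorical(df[config.category_column].astype(str), categories=cats).codes
    Z = None
    if config.covariate_columns:
        Z = df[list(config.covariate_columns)].to_numpy(float)
    return entry, exit_, event, np.asarray(codes), cats, Z


def fit(data: pd.DataFrame, config: ModelConfig = ModelConfig(),
        knots_override: dict[str, KnotSet] | None = None,
        warm_start: CHModelFit | None = None,
        compute_cov: bool = True) -> CHModelFit:
    """Fit the model, selecting the internal-knot count by AIC by default.

    ``knots_override`` fixes the knot locations (used by the bootstrap so
    resampled refits share the original knots); ``warm_start`` initialises the
    optimiser from a previous fit on comparable data.
    """
    entry, exit_, event, codes, cats, Z = _extract(data, config)
    if len(cats) == 0:
        raise ValueError("no categories present")
    shared = config.baseline == "proportional"

    cov_names = list(config.covariate_columns)
    if shared:
        # categories enter as proportional covariates, reference = first category
        dummies = np.column_stack([(codes == i).astype(float) for i in range(1, len(cats))]) \
            if len(cats) > 1 else np.empty((len(codes), 0))
        Z = dummies if Z is None else np.column_stack([dummies, Z])
        cov_names = [f"cat:{c}" for c in cats[1:]] + cov_names

    for ci, c in enumerate(cats):
        if not np.any(event[codes == ci] == 1) and not shared:
            raise ValueError(f"category {c!r} has no events; cannot fit its baseline")
    if shared and not np.any(event == 1):
        raise ValueError("no events in data")

    candidates = config.knot_candidates if config.selection == "aic" else config.knot_candidates[:1]
    if knots_override is not None:
        candidates = (None,)

    best = None
    prev = warm_start
    trace = []
    for k in candidates:
        if knots_override is not None:
            knots = dict(knots_override)
        else:
            try:
                if shared:
                    knots = {PROPORTIONAL: place_knots(exit_[event == 1], k)}
                else:
                    knots = {
                        c: place_knots(exit_[(codes == ci) & (event == 1)], k)
                        for ci, c in enumerate(cats)
                    }
            except ValueError as exc:
                trace.append(f"k={k}: {exc}")
                continue
        lik = CHLikelihood(entry, exit_, event, codes, cats, knots, Z, shared)
        starts = _initial_starts(lik, entry, exit_, event, codes, prev)
        res = _optimise(lik, starts)
        if res is None:
            trace.append(f"k={k}: optimiser failed")
            continue
        theta, ll, ok, msg = res
        fitk = _assemble(lik, theta, ll, ok, msg, cats, knots, cov_names, shared, config)
        if not _monotone(fitk, entry, exit_, config.grid_step):
            trace.append(f"k={k}: non-monotone cumulative hazard rejected")
            continue
        trace.append(f"k={k}: loglik={ll:.4f} aic={fitk.aic:.4f}")
        if best is None or fitk.aic < best.aic - 1e-9:
            best = fitk
        prev = fitk
    if best is None:
        raise ConvergenceError("no candidate model converged:\n" + "\n".join(trace))
    if compute_cov:
        best.cov = _covariance(
            CHLikelihood(entry, exit_, event, codes, cats, best.knots, Z, shared,
                         transforms=best.basis_transform),
            best,
        )
    return best


def _initial_starts(lik: CHLikelihood, entry, exit_, event, codes,
                    prev: CHModelFit | None) -> list[np.ndarray]:
    """Candidate starting points: projection of the previous fit (preserves
    the nesting of log likelihoods across knot counts), Nelson-Aalen
    regression, and a Weibull-only fallback."""
    weib = np.zeros(lik.n_params)
    na = np.zeros(lik.n_params)
    proj = np.zeros(lik.n_params) if prev is not None else None
    na_ok = False
    ofs = 0
    for ki, key in enumerate(lik.keys):
        size = lik.block_sizes[ki]
        T = lik.transforms[key]
        rows = np.arange(lik.n) if lik.shared else np.flatnonzero(codes == ki)
        wb = _weibull_start(entry[rows], exit_[rows], event[rows])
        raw_wb = np.zeros(size)
        raw_wb[:2] = wb
        weib[ofs : ofs + size] = np.linalg.solve(T, raw_wb)
        na[ofs : ofs + size] = weib[ofs : ofs + size]
        nb = _nelson_aalen_start(entry[rows], exit_[rows], event[rows], lik.knots[key])
        if nb is not None:
            na[ofs : ofs + size] = np.linalg.solve(T, nb)
            na_ok = True
        if proj is not None:
            proj[ofs : ofs + size] = weib[ofs : ofs + size]
            cat = None if lik.shared else lik.categories[ki]
            key_prev = PROPORTIONAL if prev.baseline == "proportional" else cat
            if key_prev in prev.gamma:
                lo, hi = prev.knots[key_prev].boundary
                xg = np.linspace(lo, hi, 60)
                eta_prev = (rcs_design(xg, prev.knots[key_prev])
                            @ prev._transform(key_prev) @ prev.gamma[key_prev])
                try:
                    raw = _project_start(eta_prev, xg, lik.knots[key])
                    proj[ofs : ofs + size] = np.linalg.solve(T, raw)
                except np.linalg.LinAlgError:
                    pass
        ofs += size
    if proj is not None and lik.n_beta and prev.beta.size == lik.n_beta:
        proj[-lik.n_beta :] = prev.beta
    starts = []
    if proj is not None:
        starts.append(proj)
    if na_ok:
        starts.append(na)
    starts.append(weib)
    return starts


def _lm_polish(lik: CHLikelihood, theta: np.ndarray, maxiter: int = 40):
    """Damped-Newton polish for stalled line searches.

    The slope barrier makes the curvature wildly anisotropic near the
    positivity boundary, where BFGS line searches stall; a Levenberg-damped
    Newton step on a finite-difference Hessian of the analytic gradient
    handles that region.  Returns (theta, ll) or None.
    """
    f, g = lik(theta)
    lam = 1e-3
    eye = np.eye(len(theta))
    for _ in range(maxiter):
        if np.max(np.abs(g)) < 1e-6 * max(1.0, abs(f)):
            return theta, -f
        Hm = _hessian(lik, theta, lambda t: lik(t)[1])
        accepted = False
        for _ in range(15):
            try:
                step = np.linalg.solve(Hm + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            f2, g2 = lik(theta + step)
            if np.isfinite(f2) and f2 < f:
                theta, f, g = theta + step, f2, g2
                lam = max(lam / 3, 1e-8)
                accepted = True
                break
            lam *= 10
        if not accepted:
            return None
    return (theta, -f) if np.max(np.abs(g)) < 1e-4 * max(1.0, abs(f)) else None


def _optimise(lik: CHLikelihood, starts: list[np.ndarray] | np.ndarray):
    """Quasi-Newton maximisation from one or more starts; best result wins."""
    if isinstance(starts, np.ndarray):
        starts = [starts]
    best = None
    for s in starts:
        res = optimize.minimize(lik, s, jac=True, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 600})
        gmax = float(np.max(np.abs(res.jac)))
        ll = -float(res.fun)
        if ll <= -_PENALTY / 2 or not np.isfinite(ll):
            continue
        ok = bool(res.success) or gmax < 1e-4 * max(1.0, abs(ll))
        if best is None or (ok, ll) > (best[2], best[1]):
            best = (res.x, ll, ok, str(res.message))
    if best is not None and not best[2]:
        polished = _lm_polish(lik, best[0])
        if polished is not None:
            best = (polished[0], polished[1], True, "damped-newton polish")
    return best


def _assemble(lik, theta, ll, ok, msg, cats, knots, cov_names, shared, config):
    gammas, beta = lik.unpack(theta)
    names = []
    for key, size in zip(lik.keys, lik.block_sizes):
        names += [f"{key}:g{j}" for j in range(size)]
    names += list(cov_names)
    return CHModelFit(
        categories=cats,
        knots=dict(knots),
        gamma={k: g.copy() for k, g in zip(lik.keys, gammas)},
        beta=np.asarray(beta, dtype=float).copy(),
        covariate_names=tuple(cov_names),
        loglik=ll,
        n_params=lik.n_params,
        n_subjects=lik.n,
        converged=ok,
        message=str(msg),
        param_names=tuple(names),
        baseline="proportional" if shared else "per_category",
        config=config,
        basis_transform={k: lik.transforms[k] for k in lik.keys},
    )


def _monotone(fitk: CHModelFit, entry, exit_, step: float) -> bool:
    """Accept only non-decreasing, plausibly-scaled cumulative hazards.

    Under left truncation the cumulative-hazard level is only weakly
    identified, and the likelihood has a flat ridge where an inflated level
    with a near-zero spline slope mimics the data in-range but predicts
    absurdly out of range.  Candidates on that ridge are rejected by two
    guards: the log-log slope must stay above a small margin (any monotone
    hazard on the age timescale has d ln H / d ln t well away from 0; 0.1 still
    admits anything growing at least like t^0.1), and
    H must stay below ~100 over the observed age range.
    """
    lo, hi = float(np.min(entry)), float(np.max(exit_))
    grid = np.arange(max(lo, 1e-6), hi + step, step)
    lgrid = np.log(grid)
    for key in fitk.gamma:
        coef = fitk._transform(key) @ fitk.gamma[key]
        slope = rcs_deriv(lgrid, fitk.knots[key]) @ coef
        if np.any(slope < 0.1):
            return False
        eta = rcs_design(lgrid, fitk.knots[key]) @ coef
        if np.max(eta) > 4.6:
            return False
    return True


def _covariance(lik: CHLikelihood, fitk: CHModelFit) -> np.ndarray | None:
    theta = np.concatenate([fitk.gamma[k] for k in lik.keys] + [fitk.beta])

    def grad(t):
        return lik(t)[1]

    info = _hessian(lik, theta, grad)
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# prediction and hazard ratios
# ---------------------------------------------------------------------------


def predict(fit_: CHModelFit, category: str, ages, covariates: dict[str, float] | None = None):
    """Cumulative hazard, hazard and survival curves at the given ages.

    ``covariates`` maps covariate names to values; omitted covariates are 0
    (the reference level).
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    eta = fit_.spline_eta(category, ages)
    if covariates:
        for name, val in covariates.items():
            if name not in fit_.covariate_names:
                raise ValueError(f"unknown covariate {name!r}")
            eta = eta + fit_.beta[fit_.covariate_names.index(name)] * val
    H = np.exp(eta)
    S = np.exp(-H)
    h = H * fit_.spline_slope(category, ages) / ages
    return H, h, S


def hazard_ratio(fit_: CHModelFit, category: str, reference: str):
    """Hazard ratio (with Wald 95% CI) between categories of a proportional fit."""
    if fit_.baseline != "proportional":
        raise ValueError(
            "hazard ratios require the proportional-baseline fit (categories as "
            "covariates); this fit has a separate baseline per category"
        )
    if category == reference:
        return 1.0, (1.0, 1.0)

    def coef(cat):
        name = f"cat:{cat}"
        if name in fit_.covariate_names:
            idx = fit_.covariate_names.index(name)
            pos = len(fit_.param_names) - len(fit_.covariate_names) + idx
            return fit_.beta[idx], pos
        if cat in fit_.categories:  # reference level of the fit
            return 0.0, None
        raise ValueError(f"unknown category {cat!r}")

    b1, i1 = coef(category)
    b0, i0 = coef(reference)
    diff = b1 - b0
    var = 0.0
    if fit_.cov is not None:
        if i1 is not None:
            var += fit_.cov[i1, i1]
        if i0 is not None:
            var += fit_.cov[i0, i0]
        if i1 is not None and i0 is not None:
            var -= 2 * fit_.cov[i1, i0]
    se = float(np.sqrt(max(var, 0.0)))
    hr = float(np.exp(diff))
    return hr, (float(np.exp(diff - 1.959964 * se)), float(np.exp(diff + 1.959964 * se)))
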