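"""Pulse-based drift-diffusion (accumulator) model over maze position.

The latent decision variable ``a`` evolves over maze position y (meters):
between pulses da = lambda * a * dy + sigma_a * dW, each tower contributes an
impulse of magnitude +/- eta * C where eta ~ N(1, sigma2_s) and C is the
running sensory-adaptation state, and accumulation stops at sticky bounds
+/-B.  At trial end a right choice is made if the accumulator exceeds the
``bias`` threshold, except on a ``lapse`` fraction of trials where the choice
is random.

Trial likelihoods are computed by propagating the full accumulator
distribution on a discrete a-grid with mass-conserving, moment-matched
transition kernels; absorbed bound mass is tracked separately and assigned to
the choice matching its sign.  Distances use meters (leak lambda is in 1/m);
tower positions stored in cm are converted on entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields as dataclass_fields
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import ndtr

from .datamodel import TrialRecord, ValidationError

# Fit bounds for the nine parameters (lambda in 1/m, tau_phi in m).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "lam": (-5.0, 5.0),
    "sigma2_a": (0.0, 200.0),
    "sigma2_s": (0.0, 200.0),
    "sigma2_i": (0.0, 30.0),
    "bound": (5.0, 25.0),
    "phi": (0.0, 1.2),
    "tau_phi": (0.001, 2.0),
    "bias": (-5.0, 5.0),
    "lapse": (0.0, 1.0),
}

STEM_LENGTH_M = 3.0  # propagation horizon: cue region (2 m) + delay (1 m)


@dataclass(frozen=True)
class DDMParams:
    """The nine accumulator parameters.

    lam: leak (<0) / instability (>0), 1/m.  sigma2_a: diffusion variance per
    m.  sigma2_s: per-pulse sensory variance.  sigma2_i: initial-value
    variance.  bound: sticky bound height B.  phi / tau_phi: adaptation
    multiplier and recovery constant (m).  bias: decision threshold on the
    final accumulator value.  lapse: probability of a random choice.
    """

    lam: float = 0.0
    sigma2_a: float = 1.0
    sigma2_s: float = 4.0
    sigma2_i: float = 1.0
    bound: float = 15.0
    phi: float = 1.0
    tau_phi: float = 0.5
    bias: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValidationError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)


PARAM_NAMES = [f.name for f in dataclass_fields(DDMParams)]


# ---------------------------------------------------------------------------
# Sensory adaptation


def adaptation_trace(positions_m: np.ndarray, phi: float, tau_phi: float) -> np.ndarray:
    """Effective pulse magnitudes C_i for pooled, ascending pulse positions.

    C starts at 1.  Between pulses it recovers exponentially toward 1 with
    space constant tau_phi; each pulse takes the current C as its magnitude,
    after which C is multiplied by phi (phi < 1: depression; phi > 1:
    facilitation; phi = 1: no adaptation).
    """
    if tau_phi <= 0:
        raise ValidationError("tau_phi must be positive")
    positions = np.asarray(positions_m, dtype=float)
    if np.any(np.diff(positions) < -1e-12):
        raise ValidationError("pulse positions must be ascending")
    c = 1.0
    last_y = None
    out = np.empty(len(positions))
    for i, y in enumerate(positions):
        if last_y is not None:
            c = 1.0 - (1.0 - c) * math.exp(-(y - last_y) / tau_phi)
        out[i] = c
        c *= phi
        last_y = y
    return out


def trial_pulses(
    trial: TrialRecord, phi: float, tau_phi: float, within_stream: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (m) and signed adapted magnitudes (+ = right) for one trial.

    By default both evidence streams share one adaptation process (pooled);
    ``within_stream=True`` runs adaptation separately per side.
    """
    pooled = trial.all_towers()
    if not pooled:
        return np.empty(0), np.empty(0)
    ys = np.array([p[0] for p in pooled]) / 100.0
    signs = np.array([1.0 if p[1] == "R" else -1.0 for p in pooled])
    if within_stream:
        mags = np.empty(len(ys))
        for s in (1.0, -1.0):
            sel = signs == s
            mags[sel] = adaptation_trace(ys[sel], phi, tau_phi)
    else:
        mags = adaptation_trace(ys, phi, tau_phi)
    return ys, signs * mags


# ---------------------------------------------------------------------------
# Distribution propagation


def _moment_matched_kernel(v: float, h: float) -> np.ndarray:
    """Symmetric zero-mean kernel on grid offsets with exact mass and variance v."""
    if v <= 0:
        return np.array([1.0])
    s = math.sqrt(v)
    half = max(1, int(math.ceil(5.0 * s / h)))
    edges = (np.arange(-half, half + 2) - 0.5) * h
    w = np.diff(ndtr(edges / s))
    w = w / w.sum()
    offs = np.arange(-half, half + 1) * h
    vk = float(np.sum(w * offs**2))
    dv = (v - vk) / (2.0 * h * h)
    c = half  # center index
    if dv >= 0:
        d = min(dv, w[c] / 2.0)
        w[c] -= 2 * d
        w[c - 1] += d
        w[c + 1] += d
    else:
        d = min(-dv, w[c - 1], w[c + 1])
        w[c] += 2 * d
        w[c - 1] -= d
        w[c + 1] -= d
    return w


class _Propagator:
    """Shared-grid propagation machinery for a fixed parameter set."""

    def __init__(self, params: DDMParams, dy: float, grid_points: int):
        self.params = params
        self.dy = dy
        b = params.bound
        self.grid = np.linspace(-b, b, grid_points)
        self.h = self.grid[1] - self.grid[0]
        self.interior = self.grid[1:-1]
        self.n_int = len(self.interior)
        lam = params.lam
        self.decay = math.exp(lam * dy)
        # exact one-step diffusion variance for the OU/unstable linear SDE
        if abs(lam) > 1e-12:
            self.v_step = params.sigma2_a * (math.expm1(2 * lam * dy)) / (2 * lam)
        else:
            self.v_step = params.sigma2_a * dy
        self.diff_kernel = _moment_matched_kernel(self.v_step, self.h)
        self._leak_op = self._build_leak_op() if abs(self.decay - 1.0) > 1e-15 else None
        self._impulse_cache: dict[tuple[float, float], tuple[np.ndarray, int]] = {}

    def _build_leak_op(self) -> sparse.csr_matrix:
        """Sparse map of interior mass under a -> a*decay; cols 0/-1 are sticky."""
        n = self.n_int
        xp = self.interior * self.decay
        rows, cols, vals = [], [], []
        x0 = self.interior[0]
        for j in range(n):
            x = xp[j]
            if x <= self.grid[0]:
                rows.append(j); cols.append(0); vals.append(1.0)
                continue
            if x >= self.grid[-1]:
                rows.append(j); cols.append(n + 1); vals.append(1.0)
                continue
            f = (x - x0) / self.h
            i = int(math.floor(f))
            r = f - i
            # columns shifted by 1: 0 = left sticky, 1..n = interior, n+1 = right sticky
            lo_col = i + 1 if 0 <= i < n else (0 if i < 0 else n + 1)
            hi_col = i + 2 if 0 <= i + 1 < n else (0 if i + 1 < 0 else n + 1)
            if 1.0 - r > 0:
                rows.append(j); cols.append(min(max(lo_col, 0), n + 1)); vals.append(1.0 - r)
            if r > 0:
                rows.append(j); cols.append(min(max(hi_col, 0), n + 1)); vals.append(r)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n + 2))

    def initial_state(self, n_trials: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(interior mass, left absorbed, right absorbed) for a0 ~ N(0, sigma2_i)."""
        p = np.zeros(self.n_int)
        s2 = self.params.sigma2_i
        center = self.n_int // 2  # grid is symmetric and odd-sized; interior center = 0
        if s2 <= 0:
            p[center] = 1.0
        else:
            kern = _moment_matched_kernel(s2, self.h)
            half = (len(kern) - 1) // 2
            for off, w in zip(range(-half, half + 1), kern):
                idx = center + off
                if idx < 0 or idx >= self.n_int:
                    continue  # clipped into nearest interior bin below
                p[idx] += w
            # clip tail mass into edge interior bins (bounds not yet sticky at y=0)
            tail = 1.0 - p.sum()
            p[center] += tail
        P = np.tile(p, (n_trials, 1))
        return P, np.zeros(n_trials), np.zeros(n_trials)

    def step(self, P: np.ndarray, absorbed_l: np.ndarray, absorbed_r: np.ndarray) -> tuple:
        if self._leak_op is not None:
            out = P @ self._leak_op
            absorbed_l = absorbed_l + out[:, 0]
            absorbed_r = absorbed_r + out[:, -1]
            P = out[:, 1:-1]
        kern = self.diff_kernel
        if len(kern) > 1:
            P, absorbed_l, absorbed_r = _convolve_absorb(P, kern, absorbed_l, absorbed_r)
        return P, absorbed_l, absorbed_r

    def impulse_kernel(self, mu: float, v: float) -> tuple[np.ndarray, int]:
        """Kernel (weights, leftmost offset) realizing a mean-mu, variance-v impulse."""
        key = (round(mu, 3), round(v, 3))
        if key in self._impulse_cache:
            return self._impulse_cache[key]
        h = self.h
        q = math.floor(mu / h)
        r = mu - q * h
        split_var = r * (h - r)
        shift = np.array([1.0 - r / h, r / h])
        kern = _moment_matched_kernel(max(v - split_var, 0.0), h)
        full = np.convolve(shift, kern)
        half = (len(kern) - 1) // 2
        offset = q - half  # grid offset of full[0]
        out = (full, offset)
        self._impulse_cache[key] = out
        return out

    def apply_impulse(
        self,
        P: np.ndarray,
        rows: np.ndarray,
        mu: np.ndarray,
        v: np.ndarray,
        absorbed_l: np.ndarray,
        absorbed_r: np.ndarray,
    ) -> tuple:
        for i, m, vv in zip(rows, mu, v):
            kern, off = self.impulse_kernel(float(m), float(vv))
            row = np.convolve(P[i], kern)
            # row index j corresponds to grid offset j + off relative to interior start
            lo = off
            hi = off + len(row)
            newrow = np.zeros(self.n_int)
            a, b = max(0, lo), min(self.n_int, hi)
            if a < b:
                newrow[a:b] = row[a - lo : b - lo]
            if lo < 0:
                absorbed_l[i] += row[: min(-lo, len(row))].sum()
            if hi > self.n_int:
                absorbed_r[i] += row[max(0, self.n_int - lo) :].sum()
            P[i] = newrow
        return P, absorbed_l, absorbed_r

    def finish(self, P: np.ndarray, absorbed_l: np.ndarray, absorbed_r: np.ndarray) -> np.ndarray:
        """P(choice = R) before lapse: threshold unabsorbed mass at ``bias``."""
        bias = self.params.bias
        if abs(bias) > self.params.bound:
            raise ValidationError("''|bias| > B'' puts the threshold beyond the bounds")
        x = self.interior
        above = x > bias + 1e-12
        at = np.abs(x - bias) <= 1e-12
        p_right = P[:, above].sum(axis=1) + 0.5 * P[:, at].sum(axis=1) + absorbed_r
        return p_right

    def mass(self, P, absorbed_l, absorbed_r) -> np.ndarray:
        return P.sum(axis=1) + absorbed_l + absorbed_r


def _convolve_absorb(P, kern, absorbed_l, absorbed_r):
    half = (len(kern) - 1) // 2
    n, g = P.shape
    pad = np.zeros((n, g + 2 * half))
    pad[:, half:-half] = P
    from scipy.ndimage import convolve1d

    out = convolve1d(pad, kern, axis=1, mode="constant", cval=0.0)
    absorbed_l = absorbed_l + out[:, :half].sum(axis=1)
    absorbed_r = absorbed_r + out[:, -half:].sum(axis=1)
    return out[:, half:-half], absorbed_l, absorbed_r


def ddm_pR(
    trials: Sequence[TrialRecord],
    params: DDMParams,
    dy: float = 0.01,
    grid_points: int = 281,
    within_stream: bool = False,
    mass_tol: float = 1e-8,
    return_mass_error: bool = False,
):
    """Vectorized right-choice probability for every trial.

    Pulses are applied at the nearest propagation step, with their mean and
    standard deviation rescaled by exp(lam * (y_step - y_pulse)) so the
    contribution of each pulse to the final accumulator mean is exact despite
    the step quantization.
    """
    n = len(trials)
    prop = _Propagator(params, dy, grid_points)
    n_steps = int(round(STEM_LENGTH_M / dy))

    # schedule[k] = (rows, mu, v) of pulses applied after step k
    schedule: dict[int, list[tuple[int, float, float]]] = {}
    for i, trial in enumerate(trials):
        ys, mags = trial_pulses(trial, params.phi, params.tau_phi, within_stream)
        for y, m in zip(ys, mags):
            k = min(int(round(y / dy)), n_steps)
            timing = math.exp(params.lam * (k * dy - y))
            mu = m * timing
            v = params.sigma2_s * (m * timing) ** 2
            schedule.setdefault(k, []).append((i, mu, v))

    P, al, ar = prop.initial_state(n)
    for k in range(n_steps + 1):
        if k > 0:
            P, al, ar = prop.step(P, al, ar)
        if k in schedule:
            ev = schedule[k]
            rows = np.array([e[0] for e in ev])
            mu = np.array([e[1] for e in ev])
            v = np.array([e[2] for e in ev])
            P, al, ar = prop.apply_impulse(P, rows, mu, v, al, ar)

    mass_err = np.abs(prop.mass(P, al, ar) - 1.0)
    if np.any(mass_err > mass_tol):
        raise ValidationError(
            f"probability mass leak {mass_err.max():.3e} exceeds tolerance {mass_tol:g}"
        )
    p_acc = prop.finish(P, al, ar)
    p = params.lapse / 2.0 + (1.0 - params.lapse) * p_acc
    if return_mass_error:
        return p, float(mass_err.max())
    return p


def ddm_final_mean(
    trials: Sequence[TrialRecord],
    params: DDMParams,
    dy: float = 0.01,
    grid_points: int = 281,
) -> np.ndarray:
    """Mean of the unabsorbed accumulator at trial end (diagnostics/tests)."""
    n = len(trials)
    prop = _Propagator(params, dy, grid_points)
    n_steps = int(round(STEM_LENGTH_M / dy))
    schedule: dict[int, list[tuple[int, float, float]]] = {}
    for i, trial in enumerate(trials):
        ys, mags = trial_pulses(trial, params.phi, params.tau_phi)
        for y, m in zip(ys, mags):
            k = min(int(round(y / dy)), n_steps)
            timing = math.exp(params.lam * (k * dy - y))
            schedule.setdefault(k, []).append((i, m * timing, params.sigma2_s * (m * timing) ** 2))
    P, al, ar = prop.initial_state(n)
    for k in range(n_steps + 1):
        if k > 0:
            P, al, ar = prop.step(P, al, ar)
        if k in schedule:
            ev = schedule[k]
            rows = np.array([e[0] for e in ev])
            mu = np.array([e[1] for e in ev])
            v = np.array([e[2] for e in ev])
            P, al, ar = prop.apply_impulse(P, rows, mu, v, al, ar)
    unabsorbed = P.sum(axis=1)
    mean = P @ prop.interior
    return mean / np.maximum(unabsorbed, 1e-300)


def ddm_trial_pR(trial: TrialRecord, params: DDMParams, **kwargs) -> float:
    return float(ddm_pR([trial], params, **kwargs)[0])


LIKELIHOOD_FLOOR = 1e-10


def ddm_loglik(
    trials: Sequence[TrialRecord],
    params: DDMParams,
    dy: float = 0.01,
    grid_points: int = 281,
    **kwargs,
) -> float:
    """Bernoulli log likelihood of the observed choices under the model."""
    p = ddm_pR(trials, params, dy=dy, grid_points=grid_points, **kwargs)
    c = np.array([1.0 if t.choice == "R" else 0.0 for t in trials])
    like = np.where(c == 1.0, p, 1.0 - p)
    return float(np.sum(np.log(np.maximum(like, LIKELIHOOD_FLOOR))))


@dataclass
class DDMFit:
    params: DDMParams
    loglik: float
    converged: bool
    n_trials: int
    free_names: list
    starts: list  # (start params array, final neg loglik, success) per start
    dy: float
    grid_points: int
    mass_error: float


def fit_ddm(
    trials: Sequence[TrialRecord],
    free: Optional[Sequence[str]] = None,
    fixed: Optional[DDMParams] = None,
    n_starts: int = 4,
    rng: Optional[np.random.Generator] = None,
    dy: float = 0.02,
    grid_points: int = 161,
    bounds: Optional[dict] = None,
    maxiter: int = 200,
) -> DDMFit:
    """Bounded maximum-likelihood fit from multiple random interior starts.

    ``free`` names the parameters being optimized (default: all nine);
    the rest are held at ``fixed`` (default: DDMParams defaults).  Gradients
    are finite-difference; the best optimum across starts is returned along
    with all per-start results.
    """
    rng = rng or np.random.default_rng()
    free = list(free) if free is not None else list(PARAM_NAMES)
    base = fixed or DDMParams()
    bnds = dict(PARAM_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[n][0] for n in free])
    hi = np.array([bnds[n][1] for n in free])
    span = hi - lo

    # optimize in unit-scaled coordinates so finite-difference steps are
    # commensurate across parameters with very different natural scales
    def build(u: np.ndarray) -> DDMParams:
        x = lo + np.clip(u, 0.0, 1.0) * span
        return replace(base, **{n: float(v) for n, v in zip(free, x)})

    def objective(u: np.ndarray) -> float:
        try:
            return -ddm_loglik(trials, build(u), dy=dy, grid_points=grid_points)
        except ValidationError:
            return 1e12

    starts = []
    u0_default = np.clip((base.as_array(free) - lo) / span, 0.02, 0.98)
    start_points = [u0_default] + [
        rng.uniform(0.1, 0.9, size=len(free)) for _ in range(n_starts - 1)
    ]
    best = None
    for u0 in start_points:
        res = minimize(
            objective,
            u0,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * len(free),
            options={"maxiter": maxiter, "eps": 2e-3},
        )
        starts.append((u0.copy(), float(res.fun), bool(res.success)))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ValidationError("all optimization starts failed")
    params = build(best.x)
    _, mass_err = ddm_pR(trials, params, dy=dy, grid_points=grid_points, return_mass_error=True)
    return DDMFit(
        params=params,
        loglik=-float(best.fun),
        converged=any(s[2] for s in starts),
        n_trials=len(trials),
        free_names=free,
        starts=starts,
        dy=dy,
        grid_points=grid_points,
        mass_error=mass_err,
    )
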