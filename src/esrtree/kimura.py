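"""Time-dependent diffusion of an allele frequency under pure drift.

The transition distribution of a neutral allele frequency after drift time
tau = t/(2Ne) is a mixture of an atom at 0 (loss), an atom at 1 (fixation)
and a continuous density on (0,1).  The continuous part is the classical
eigenfunction expansion of the drift diffusion,

    f(x | p, tau) = sum_{i>=1} p q (i+1)(2i+1)/i
                    * P_{i-1}(1-2p) P_{i-1}(1-2x) exp(-i(i+1) tau / 2),

where q = 1 - p and P_n is the Jacobi polynomial P_n^{(1,1)} (the Gegenbauer
form of the expansion).  The absorption probabilities are the matching
series

    P(lost by tau)  = q - p q sum_{i>=1} (2i+1)/i P_{i-1}(1-2p) e_i,
    P(fixed by tau) = p + p q sum_{i>=1} (-1)^i (2i+1)/i P_{i-1}(1-2p) e_i,

with e_i = exp(-i(i+1) tau / 2).  For very small tau the series converges
slowly and suffers catastrophic cancellation, so below ``TAU_SMALL`` the
kernel switches to a truncated-Gaussian surrogate with matched mean p and
variance p q tau; the tail mass outside (0,1) is assigned to the atoms.

For use inside Metropolis ratios over the mixed state space, the two atoms
are lumped onto pseudo-intervals of width ``atom_width`` at each end of
[0,1], giving an ordinary density that standard reflected random-walk
proposals can explore (see :func:`log_kernel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

TAU_SMALL = 0.005
_EXP_CUTOFF = 72.0  # series truncated once i(i+1)*tau exceeds this
_MAX_TERMS = 600
_LOG_FLOOR = -745.0
_DENS_FLOOR = 1e-300


@njit(cache=True)
def _n_terms(tau: float) -> int:
    # smallest i with i(i+1)*tau >= _EXP_CUTOFF, clamped to [12, _MAX_TERMS]
    i = int(math.ceil(0.5 * (-1.0 + math.sqrt(1.0 + 4.0 * _EXP_CUTOFF / tau))))
    if i < 12:
        i = 12
    if i > _MAX_TERMS:
        i = _MAX_TERMS
    return i


@njit(cache=True)
def _coefs(tau: float):
    """Per-term factors for the eigen-series and the Jacobi recurrence.

    cd[i] = (i+1)(2i+1)/i * e_i (density), cm[i] = (2i+1)/i * e_i (masses)
    with e_i = exp(-i(i+1)tau/2); ra/rb are the division-free three-term
    recurrence multipliers for P_{i-1}^{(1,1)}.
    """
    m = _n_terms(tau)
    cd = np.empty(m + 1)
    cm = np.empty(m + 1)
    ra = np.empty(m + 1)
    rb = np.empty(m + 1)
    for i in range(1, m + 1):
        e = math.exp(-0.5 * i * (i + 1) * tau)
        cd[i] = (i + 1.0) * (2.0 * i + 1.0) / i * e
        cm[i] = (2.0 * i + 1.0) / i * e
        n = i - 1.0  # degree of the polynomial appearing at term i
        if n >= 2.0:
            ra[i] = (n + 1.0) * (2.0 * n + 1.0) / (n * (n + 2.0))
            rb[i] = n * (n + 1.0) / (n * (n + 2.0))
        else:
            ra[i] = 0.0
            rb[i] = 0.0
    return cd, cm, ra, rb


@njit(cache=True, fastmath=True)
def _series_point(p: float, x: float, tau: float, cd, cm, ra, rb):
    """Continuous density at x plus absorption masses, series regime."""
    q = 1.0 - p
    if p <= 0.0:
        return 0.0, 1.0, 0.0
    if p >= 1.0:
        return 0.0, 0.0, 1.0
    zp = 1.0 - 2.0 * p
    zx = 1.0 - 2.0 * x
    m = cd.shape[0] - 1
    sd = 0.0
    sl = 0.0
    sf = 0.0
    pp1 = 1.0
    pp2 = 0.0
    px1 = 1.0
    px2 = 0.0
    sign = -1.0
    for i in range(1, m + 1):
        if i == 1:
            pp = 1.0
            px = 1.0
        elif i == 2:
            pp = 2.0 * zp
            px = 2.0 * zx
        else:
            pp = ra[i] * zp * pp1 - rb[i] * pp2
            px = ra[i] * zx * px1 - rb[i] * px2
        sd += cd[i] * pp * px
        sl += cm[i] * pp
        sf += sign * cm[i] * pp
        sign = -sign
        pp2 = pp1
        pp1 = pp
        px2 = px1
        px1 = px
    dens = p * q * sd
    if dens < 0.0:
        dens = 0.0
    lost = q - p * q * sl
    fixed = p + p * q * sf
    if lost < 0.0:
        lost = 0.0
    if lost > 1.0:
        lost = 1.0
    if fixed < 0.0:
        fixed = 0.0
    if fixed > 1.0:
        fixed = 1.0
    return dens, lost, fixed


@njit(cache=True, inline="always")
def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


@njit(cache=True)
def _gauss_point(p: float, x: float, tau: float):
    """Small-tau surrogate: Gaussian(p, pq*tau) with tails lumped on atoms."""
    q = 1.0 - p
    if p <= 0.0:
        return 0.0, 1.0, 0.0
    if p >= 1.0:
        return 0.0, 0.0, 1.0
    s = math.sqrt(p * q * tau)
    z = (x - p) / s
    dens = math.exp(-0.5 * z * z) / (s * math.sqrt(2.0 * math.pi))
    lost = _norm_cdf((0.0 - p) / s)
    fixed = 1.0 - _norm_cdf((1.0 - p) / s)
    return dens, lost, fixed


@njit(cache=True)
def _point(p: float, x: float, tau: float, cd, cm, ra, rb):
    if tau < TAU_SMALL:
        return _gauss_point(p, x, tau)
    return _series_point(p, x, tau, cd, cm, ra, rb)


@njit(cache=True, inline="always")
def _lump(dens: float, lost: float, fixed: float, x: float, w: float) -> float:
    f = dens
    if x <= w:
        f += lost / w
    if x >= 1.0 - w:
        f += fixed / w
    if f < _DENS_FLOOR:
        return _LOG_FLOOR
    return math.log(f)


@njit(cache=True)
def _logk_vec(p: np.ndarray, x: np.ndarray, tau: float, w: float) -> np.ndarray:
    """log lumped kernel density, elementwise over SNPs."""
    cd, cm, ra, rb = _coefs(tau)
    out = np.empty(p.shape[0])
    for j in range(p.shape[0]):
        dens, lost, fixed = _point(p[j], x[j], tau, cd, cm, ra, rb)
        out[j] = _lump(dens, lost, fixed, x[j], w)
    return out


@njit(cache=True)
def _logk_vec_pair_x(
    p: np.ndarray, x1: np.ndarray, x2: np.ndarray, tau: float, w: float
):
    """log kernel at two descendant vectors sharing the same ancestors."""
    cd, cm, ra, rb = _coefs(tau)
    n = p.shape[0]
    o1 = np.empty(n)
    o2 = np.empty(n)
    for j in range(n):
        d1, l1, f1 = _point(p[j], x1[j], tau, cd, cm, ra, rb)
        d2, l2, f2 = _point(p[j], x2[j], tau, cd, cm, ra, rb)
        o1[j] = _lump(d1, l1, f1, x1[j], w)
        o2[j] = _lump(d2, l2, f2, x2[j], w)
    return o1, o2


@njit(cache=True)
def _logk_vec_pair_p(
    p1: np.ndarray, p2: np.ndarray, x: np.ndarray, tau: float, w: float
):
    """log kernel under two alternative ancestor vectors, same descendants."""
    cd, cm, ra, rb = _coefs(tau)
    n = x.shape[0]
    o1 = np.empty(n)
    o2 = np.empty(n)
    for j in range(n):
        d1, l1, f1 = _point(p1[j], x[j], tau, cd, cm, ra, rb)
        d2, l2, f2 = _point(p2[j], x[j], tau, cd, cm, ra, rb)
        o1[j] = _lump(d1, l1, f1, x[j], w)
        o2[j] = _lump(d2, l2, f2, x[j], w)
    return o1, o2


def _check_inputs(p: float, tau: float) -> None:
    if not (np.isfinite(p) and 0.0 <= p <= 1.0):
        raise ValueError(f"ancestral frequency p={p} outside [0, 1]")
    if not (np.isfinite(tau) and tau >= 0.0):
        raise ValueError(f"drift time tau={tau} must be non-negative")


def kimura_density(p: float, tau: float, x) -> float | np.ndarray:
    """Continuous part of the drift transition density at interior x.

    Parameters
    ----------
    p : ancestral allele frequency in [0, 1].
    tau : drift time t/(2Ne), must be > 0.
    x : frequency (scalar or array) strictly inside (0, 1).
    """
    _check_inputs(p, tau)
    if tau <= 0.0:
        raise ValueError("tau must be strictly positive for the density")
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any((xs <= 0.0) | (xs >= 1.0)) or not np.all(np.isfinite(xs)):
        raise ValueError("x must lie strictly inside (0, 1)")
    cd, cm, ra, rb = _coefs(tau)
    out = np.empty(xs.shape[0])
    for j in range(xs.shape[0]):
        out[j] = _point(p, xs[j], tau, cd, cm, ra, rb)[0]
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def boundary_masses(p: float, tau: float) -> tuple[float, float]:
    """Probabilities of loss (x=0) and fixation (x=1) by drift time tau."""
    _check_inputs(p, tau)
    if tau == 0.0:
        return (1.0, 0.0) if p == 0.0 else ((0.0, 1.0) if p == 1.0 else (0.0, 0.0))
    cd, cm, ra, rb = _coefs(max(tau, TAU_SMALL))
    _, lost, fixed = _point(p, 0.5, tau, cd, cm, ra, rb)
    return lost, fixed


@dataclass
class DriftKernelResult:
    """Full mixed drift transition distribution given (p, tau)."""

    p: float
    tau: float
    mass_lost: float
    mass_fixed: float
    density: Callable[[np.ndarray], np.ndarray]


def drift_kernel(p: float, tau: float) -> DriftKernelResult:
    lost, fixed = boundary_masses(p, tau)
    return DriftKernelResult(
        p=p,
        tau=tau,
        mass_lost=lost,
        mass_fixed=fixed,
        density=lambda x: kimura_density(p, tau, x),
    )


def log_kernel(p, tau: float, x, atom_width: float = 0.005):
    """Log of the atom-lumped drift kernel, defined on all of [0, 1].

    The loss and fixation atoms are spread uniformly over [0, atom_width]
    and [1 - atom_width, 1], so interior<->boundary Metropolis proposals
    have finite ratios.  Returns -inf-like floor (not an exception) where
    the kernel carries no mass, e.g. p = 0 with x > atom_width.
    """
    if not (0.0 < atom_width < 0.5):
        raise ValueError("atom_width must lie in (0, 0.5)")
    if not (np.isfinite(tau) and tau > 0.0):
        raise ValueError("tau must be positive and finite")
    ps = np.atleast_1d(np.asarray(p, dtype=float))
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    ps, xs = np.broadcast_arrays(ps, xs)
    if np.any((ps < 0) | (ps > 1)) or np.any((xs < 0) | (xs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    out = _logk_vec(
        np.ascontiguousarray(ps, dtype=float),
        np.ascontiguousarray(xs, dtype=float),
        float(tau),
        float(atom_width),
    )
    if np.ndim(p) == 0 and np.ndim(x) == 0:
        return float(out[0])
    return out


def wright_fisher_oracle(N: int, t: int, p0: float) -> np.ndarray:
    """Exact t-generation Wright-Fisher transition distribution (test oracle).

    Returns the probability vector over allele counts {0, 1, ..., 2N}
    starting from the lattice state nearest 2N*p0, under the binomial
    Wright-Fisher chain with 2N genes.
    """
    if N > 500:
        raise ValueError("N too large for the dense matrix oracle")
    if t < 0:
        raise ValueError("t must be non-negative")
    two_n = 2 * N
    start = int(round(two_n * p0))
    v = np.zeros(two_n + 1)
    v[start] = 1.0
    if t == 0:
        return v
    from scipy.stats import binom

    freqs = np.arange(two_n + 1) / two_n
    # row k: Binomial(2N, k/2N) pmf over 0..2N
    trans = binom.pmf(np.arange(two_n + 1)[None, :], two_n, freqs[:, None])
    return v @ np.linalg.matrix_power(trans, t)
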