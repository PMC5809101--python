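"""Ancestral lineage counts and the probability that a site is polymorphic.

A SNP dataset contains, by construction, only sites that segregate in the
pooled sample.  Conditioning the likelihood on that event requires the
probability that a site is polymorphic given the root allele frequency, the
tree and the branch lengths.  Looking backward in time, the sampled gene
copies of each population coalesce into a random number of ancestral
lineages at the root; the site is monomorphic in the sample exactly when
all those root lineages carry the same allele.  The machinery here:

* the distribution of the number of ancestral lineages of a sample of i
  genes after drift time tau (Tavare's exact alternating series as a test
  oracle, and Griffiths' normal approximation for production use, which is
  numerically stable for large i);
* the convolution of daughter-node lineage counts at internal nodes;
* the leaf-to-root recursion producing the root lineage-count distribution;
* the polymorphism probability
  P(polymorphic | x_r) = 1 - sum_k P(k) [(1-x_r)^k + x_r^k].

Throughout, tau is on the diffusion scale t/(2Ne), on which a pair of
lineages coalesces at rate 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import ndtr

_TRUNC_MASS = 1e-10


@dataclass
class LineageCountDistribution:
    """Probability distribution over the number of ancestral lineages k.

    ``support`` is a contiguous integer range; ``probs`` sums to 1.
    """

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.shape != self.probs.shape or self.support.ndim != 1:
            raise ValueError("support and probs must be matching 1-D arrays")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def truncated(self, mass: float = _TRUNC_MASS) -> "LineageCountDistribution":
        """Drop upper-tail states carrying less than ``mass`` in total."""
        cum = np.cumsum(self.probs[::-1])[::-1]
        keep = cum > mass
        keep[0] = True
        sup = self.support[keep]
        pr = self.probs[keep]
        return LineageCountDistribution(sup, pr / pr.sum())


def point_mass(k: int) -> LineageCountDistribution:
    return LineageCountDistribution(np.array([k]), np.array([1.0]))


def _griffiths_moments(i: int, tau: float) -> tuple[float, float]:
    """Asymptotic mean and variance of the ancestral lineage count.

    Griffiths' normal approximation to the line-of-descent process: with
    alpha = i*tau/2 and beta = -tau/2,

        eta   = alpha*beta / (alpha*exp(beta) - alpha + beta*exp(beta))
        mean  = 2*eta/tau
        var   = 2*eta/tau * (eta+beta)^2 / beta^2
                * (1 + eta/(eta+beta) - eta/alpha - eta/(alpha+beta) - 2*eta)

    For tau -> 0 the mean reduces to the familiar i / (1 + i*tau/2) decay.
    """
    alpha = 0.5 * i * tau
    beta = -0.5 * tau
    eb = np.exp(beta)
    denom = alpha * eb - alpha + beta * eb
    eta = alpha * beta / denom
    mean = 2.0 * eta / tau
    var = (
        2.0
        * eta
        / tau
        * (eta + beta) ** 2
        / beta**2
        * (1.0 + eta / (eta + beta) - eta / alpha - eta / (alpha + beta) - 2.0 * eta)
    )
    return float(mean), float(max(var, 1e-12))


def exact_lineage_mean(i: int, tau: float) -> float:
    """Exact E[number of ancestral lineages], by a stable positive series.

    E[A_i(tau)] = sum_{j=1}^{i} exp(-j(j-1)tau/2) (2j-1) i_[j] / i_(j),
    with i_[j] falling and i_(j) rising factorials entering only through
    the well-behaved ratio, so the sum is safe in double precision for any
    i (unlike the alternating series for the full distribution).
    """
    s = 0.0
    ratio = 1.0
    for j in range(1, i + 1):
        ratio *= (i - j + 1) / (i + j - 1)
        term = np.exp(-0.5 * j * (j - 1) * tau) * (2 * j - 1) * ratio
        s += term
        if term < 1e-14 * s:
            break
    return float(s)


_EXACT_MAX_I = 12  # alternating series safe in double precision up to here


@njit(cache=True)
def _tavare_small(i: int, tau: float) -> np.ndarray:
    """Exact lineage-count probabilities for small i (double precision)."""
    probs = np.zeros(i)
    for k in range(1, i + 1):
        s = 0.0
        for j in range(k, i + 1):
            rising_k = 1.0  # k_(j-1)
            for m in range(j - 1):
                rising_k *= k + m
            falling_i = 1.0  # i_[j]
            rising_i = 1.0  # i_(j)
            for m in range(j):
                falling_i *= i - m
                rising_i *= i + m
            fact_k = 1.0
            for m in range(2, k + 1):
                fact_k *= m
            fact_jk = 1.0
            for m in range(2, j - k + 1):
                fact_jk *= m
            sign = -1.0 if (j - k) % 2 else 1.0
            s += (
                math.exp(-0.5 * j * (j - 1) * tau)
                * (2 * j - 1)
                * sign
                * rising_k
                * falling_i
                / (fact_k * fact_jk * rising_i)
            )
        probs[k - 1] = max(s, 0.0)
    return probs / probs.sum()


def lineage_distribution(i: int, tau: float) -> LineageCountDistribution:
    """Distribution of ancestral lineage counts of i lineages after time tau.

    Normal approximation in the spirit of Griffiths' line-of-descent
    asymptotics, discretized by binning the normal CDF at half-integer
    boundaries over {1, ..., i} and renormalizing.  The mean is computed
    exactly (stable series, :func:`exact_lineage_mean`), which removes the
    dominant bias of the asymptotic moments at moderate i; the variance
    uses Griffiths' asymptotic expression.  Exact limits are honored:
    tau = 0 gives a point mass at i, a single lineage stays single, and
    small i (where the alternating exact series is numerically safe and
    the normal approximation coarsest) uses Tavare's distribution exactly.
    """
    if i < 1:
        raise ValueError("lineage count must be >= 1")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if i == 1 or tau == 0.0:
        return point_mass(i if tau == 0.0 else 1)
    if i <= _EXACT_MAX_I:
        # Tavare's alternating series is stable in double precision for
        # small i; the normal approximation is coarse on few atoms
        probs = _tavare_small(i, tau)
        return LineageCountDistribution(
            np.arange(1, i + 1), probs
        ).truncated()
    _, var = _griffiths_moments(i, tau)
    mean = exact_lineage_mean(i, tau)
    sd = np.sqrt(var)
    ks = np.arange(1, i + 1)
    upper = (ks + 0.5 - mean) / sd
    lower = (ks - 0.5 - mean) / sd
    probs = ndtr(upper) - ndtr(lower)
    probs[0] = ndtr(upper[0])
    probs[-1] = 1.0 - ndtr(lower[-1])
    total = probs.sum()
    if total <= 0.0:
        return point_mass(int(np.clip(round(mean), 1, i)))
    return LineageCountDistribution(ks, probs / total).truncated()


def tavare_exact(i: int, tau: float) -> LineageCountDistribution:
    """Exact ancestral lineage-count distribution via the alternating series.

    High-precision evaluation (mpmath) of

        P(k | i, tau) = sum_{j=k}^{i} exp(-j(j-1)tau/2) (2j-1)(-1)^{j-k}
                        k_{(j-1)} i_{[j]} / (k! (j-k)! i_{(j)})

    with a_(b) rising and a_[b] falling factorials.  Test oracle only; the
    alternating sum is unstable in double precision for moderate i.
    """
    if i < 1:
        raise ValueError("lineage count must be >= 1")
    if i > 60:
        raise ValueError("tavare_exact limited to i <= 60 (test oracle)")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if i == 1 or tau == 0.0:
        return point_mass(i if tau == 0.0 else 1)
    import mpmath as mp

    with mp.workdps(80):
        t = mp.mpf(tau)
        probs = []
        for k in range(1, i + 1):
            s = mp.mpf(0)
            for j in range(k, i + 1):
                term = (
                    mp.e ** (-j * (j - 1) * t / 2)
                    * (2 * j - 1)
                    * (-1) ** (j - k)
                    * mp.rf(k, j - 1)
                    * mp.ff(i, j)
                    / (mp.factorial(k) * mp.factorial(j - k) * mp.rf(i, j))
                )
                s += term
            probs.append(float(s))
    pr = np.clip(np.array(probs), 0.0, None)
    return LineageCountDistribution(np.arange(1, i + 1), pr / pr.sum())


def combine_daughters(
    dists: list[LineageCountDistribution],
) -> LineageCountDistribution:
    """Distribution of the total lineage count entering a shared ancestor.

    Daughter counts are independent, so the combined distribution is their
    discrete convolution; the support starts at the number of daughters.
    """
    if not dists:
        raise ValueError("need at least one daughter distribution")
    probs = dists[0].probs
    lo = int(dists[0].support[0])
    for d in dists[1:]:
        probs = np.convolve(probs, d.probs)
        lo += int(d.support[0])
    support = np.arange(lo, lo + probs.size)
    return LineageCountDistribution(support, probs / probs.sum())


@njit(cache=True)
def _thin_dense(probs: np.ndarray, tau: float) -> np.ndarray:
    """Jitted branch thinning on a dense count-indexed probability vector.

    ``probs[k]`` is the probability of k current lineages (index 0 unused);
    returns the same representation after coalescence over time tau.  Same
    normal approximation as :func:`lineage_distribution`, inlined for speed
    (this runs inside every branch-length Metropolis proposal).
    """
    kmax = probs.shape[0] - 1
    out = np.zeros(kmax + 1)
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    for k in range(1, kmax + 1):
        p = probs[k]
        if p <= 1e-300:
            continue
        if k == 1 or tau == 0.0:
            out[k if tau == 0.0 else 1] += p
            continue
        if k <= _EXACT_MAX_I:
            exact = _tavare_small(k, tau)
            for kk in range(1, k + 1):
                out[kk] += p * exact[kk - 1]
            continue
        # exact mean, stable positive series
        mean = 0.0
        ratio = 1.0
        for j in range(1, k + 1):
            ratio *= (k - j + 1) / (k + j - 1)
            term = math.exp(-0.5 * j * (j - 1) * tau) * (2 * j - 1) * ratio
            mean += term
            if term < 1e-14 * mean:
                break
        # Griffiths asymptotic variance
        alpha = 0.5 * k * tau
        beta = -0.5 * tau
        eb = math.exp(beta)
        eta = alpha * beta / (alpha * eb - alpha + beta * eb)
        var = (
            2.0
            * eta
            / tau
            * (eta + beta) ** 2
            / beta**2
            * (
                1.0
                + eta / (eta + beta)
                - eta / alpha
                - eta / (alpha + beta)
                - 2.0 * eta
            )
        )
        if var < 1e-12:
            var = 1e-12
        sd = math.sqrt(var)
        # CDF-binned at half-integers, tails lumped into 1 and k
        prev = 0.0
        for kk in range(1, k + 1):
            if kk < k:
                cdf = 0.5 * (1.0 + math.erf((kk + 0.5 - mean) / sd * inv_sqrt2))
            else:
                cdf = 1.0
            out[kk] += p * (cdf - prev)
            prev = cdf
    return out


def _dense_to_dist(dense: np.ndarray) -> LineageCountDistribution:
    nz = np.nonzero(dense > 0.0)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    probs = dense[lo : hi + 1]
    return LineageCountDistribution(
        np.arange(lo, hi + 1), probs / probs.sum()
    ).truncated()


def _thin(dist: LineageCountDistribution, tau: float) -> LineageCountDistribution:
    """Propagate a lineage-count distribution through one branch of length tau."""
    if tau == 0.0:
        return dist
    kmax = int(dist.support[-1])
    dense = np.zeros(kmax + 1)
    dense[dist.support] = dist.probs
    return _dense_to_dist(_thin_dense(dense, tau))


def root_lineage_distribution(
    tree, tau: np.ndarray, n: np.ndarray
) -> LineageCountDistribution:
    """Lineage-count distribution at the root, by leaf-to-root recursion.

    Parameters
    ----------
    tree:
        A :class:`~esrtree.datamodel.PopulationTree`.
    tau:
        Branch lengths for one genetic system; ``tau[i]`` is the length of
        the branch above node i (1-based ids; the root entry is unused).
    n:
        Per-population lineage (gene) counts, length I.  Following the
        equal-sample-size convention, these are the maximum observed sample
        sizes, shared across sites.

    Each leaf starts from a point mass at its sample size and is thinned
    along its branch; internal nodes convolve their daughters and are
    thinned along their own branch; the root only convolves (there is no
    branch above the root).
    """
    tau = np.asarray(tau, dtype=float)
    n = np.asarray(n, dtype=np.int64)
    if n.shape[0] != tree.n_leaves:
        raise ValueError("n must give one lineage count per sampled population")
    if tau.shape[0] < tree.n_nodes:
        raise ValueError("tau must cover all non-root branches (1-based ids)")
    incoming: dict[int, LineageCountDistribution] = {}
    for node in tree.postorder():
        if not tree.children[node]:
            dist = point_mass(int(n[node - 1]))
        else:
            dist = combine_daughters([incoming[c] for c in tree.children[node]])
        if node != tree.root:
            dist = _thin(dist, float(tau[node]))
        incoming[node] = dist
    return incoming[tree.root]


def _poly_terms(x: np.ndarray, support: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """sum_k P(k) [(1-x)^k + x^k] over a contiguous support, via cumprod."""
    x = np.clip(x, 1e-15, 1.0 - 1e-15)
    k0 = int(support[0])
    K = support.shape[0]
    q = 1.0 - x
    pow_x = np.empty((K, x.shape[0]))
    pow_q = np.empty((K, x.shape[0]))
    pow_x[0] = x**k0
    pow_q[0] = q**k0
    for i in range(1, K):
        pow_x[i] = pow_x[i - 1] * x
        pow_q[i] = pow_q[i - 1] * q
    return probs @ pow_x + probs @ pow_q


def _trim_dense(dense: np.ndarray, mass: float = _TRUNC_MASS) -> np.ndarray:
    """Drop the upper tail carrying less than ``mass``, renormalize."""
    tail = np.cumsum(dense[::-1])[::-1]
    keep = np.nonzero(tail > mass)[0]
    hi = int(keep[-1]) if keep.size else dense.shape[0] - 1
    out = dense[: hi + 1].copy()
    return out / out.sum()


class RootLineageCache:
    """Incremental leaf-to-root lineage recursion for one genetic system.

    The sampler proposes one branch length at a time; only the path from
    the changed node to the root needs recomputing, so each node's
    outgoing (post-thinning) distribution is cached as a dense
    count-indexed vector.  ``propose`` evaluates a candidate branch length
    without mutating the cache; ``commit`` applies it.
    """

    def __init__(self, tree, tau: np.ndarray, n: np.ndarray):
        self.tree = tree
        self.tau = np.asarray(tau, dtype=float).copy()
        self.n = np.asarray(n, dtype=np.int64)
        self.out: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node != tree.root:
                self.out[node] = self._outgoing(node, float(self.tau[node]))
        self.root_dist = self._root(self.out)

    def _combined(self, node: int, out: dict[int, np.ndarray]) -> np.ndarray:
        kids = self.tree.children[node]
        if not kids:
            k = int(self.n[node - 1])
            dense = np.zeros(k + 1)
            dense[k] = 1.0
            return dense
        acc = out[kids[0]]
        for c in kids[1:]:
            acc = np.convolve(acc, out[c])
        return acc

    def _outgoing(self, node: int, tau_node: float,
                  out: dict[int, np.ndarray] | None = None) -> np.ndarray:
        dense = self._combined(node, out if out is not None else self.out)
        return _trim_dense(_thin_dense(dense, tau_node))

    def _root(self, out: dict[int, np.ndarray]) -> LineageCountDistribution:
        return _dense_to_dist(self._combined(self.tree.root, out))

    def propose(
        self, node: int, tau_new: float
    ) -> tuple[LineageCountDistribution, dict[int, np.ndarray]]:
        updates = {node: self._outgoing(node, tau_new)}
        trial = {**self.out, **updates}
        a = self.tree.parent[node]
        while a != self.tree.root:
            updates[a] = self._outgoing(a, float(self.tau[a]), trial)
            trial[a] = updates[a]
            a = self.tree.parent[a]
        return self._root(trial), updates

    def commit(
        self,
        node: int,
        tau_new: float,
        updates: dict[int, np.ndarray],
        root_dist: LineageCountDistribution,
    ) -> None:
        self.tau[node] = tau_new
        self.out.update(updates)
        self.root_dist = root_dist


def prob_polymorphic(x_r, root_dist: LineageCountDistribution):
    """Probability that the pooled sample is polymorphic given x_r at the root.

    1 - sum_k P(k) [(1 - x_r)^k + x_r^k]; vectorized over x_r, zero at the
    boundaries x_r = 0 and x_r = 1.
    """
    x = np.atleast_1d(np.asarray(x_r, dtype=float))
    if np.any((x < 0) | (x > 1)):
        raise ValueError("root frequency must lie in [0, 1]")
    boundary = (x == 0.0) | (x == 1.0)
    mono = _poly_terms(x, root_dist.support, root_dist.probs)
    out = np.clip(1.0 - mono, 0.0, 1.0)
    out[boundary] = 0.0
    if np.ndim(x_r) == 0:
        return float(out[0])
    return out


def log_prob_polymorphic(x_r, root_dist: LineageCountDistribution):
    """log of :func:`prob_polymorphic`, floored to avoid -inf at boundaries."""
    p = np.maximum(prob_polymorphic(x_r, root_dist), 1e-300)
    return np.log(p)
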