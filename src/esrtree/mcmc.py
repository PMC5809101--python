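"""Component-wise Metropolis-within-Gibbs sampler for the joint ESR model.

The posterior couples two data layers (autosomal "A" and X-linked "X").
Each layer carries latent allele frequencies x_ij at every node of the
tree, per-branch drift times tau_i, and a Beta(alpha, beta) root-frequency
prior re-parameterized as mu = alpha/(alpha+beta) ~ U(0,1) and
nu = alpha+beta ~ Exp(1).  The two layers are tied only through the joint
branch-length prior: (tau_A, tau_X) is uniform on the wedge
9 tau_X/16 < tau_A < 9 tau_X/8 (0 < ESR < 1) intersected with the box
[1e-4, 10]^2.  The likelihood of each layer is conditioned on SNP
polymorphism through the factor P(lambda_j = 1 | x_rj, tau, n)^-1
evaluated at the per-site root frequency.

Proposal schedule per iteration (fixed order, one seeded generator):

1. per system, one sweep of reflected random-walk updates of x at every
   node (all SNPs of a node updated in one vectorized Metropolis step;
   sites are conditionally independent given the shared parameters);
2. per system, Metropolis updates of mu (reflected into (0,1)) and nu
   (log-scale walk with Jacobian);
3. per branch, a joint (tau_A, tau_X) proposal: tau_A is reflected into
   the wedge section allowed by the current tau_X, then tau_X into the
   section allowed by the proposed tau_A, and the pair is accepted or
   rejected together.

Absorbed frequencies are handled by the atom-lumped drift kernel (see
:mod:`esrtree.kimura`): boundary mass is spread over a strip of width
``atom_width`` = 1/(2 n_max), so ordinary reflected proposals traverse
interior and absorbed states with finite ratios.

Proposal half-widths are tuned by short pilot runs (x1.25 / /1.25 per
pilot outside the target acceptance band) and frozen before burn-in.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from esrtree.datamodel import AlleleCountMatrix, PopulationTree, RunConfig
from esrtree.kimura import _logk_vec, _logk_vec_pair_p, _logk_vec_pair_x
from esrtree.lineages import (
    LineageCountDistribution,
    RootLineageCache,
    log_prob_polymorphic,
    root_lineage_distribution,
)

logger = logging.getLogger("esrtree.mcmc")

SYSTEMS = ("A", "X")

# wedge: 9 tau_X/16 < tau_A < 9 tau_X/8  <=>  8 tau_A/9 < tau_X < 16 tau_A/9
_A_LO, _A_HI = 9.0 / 16.0, 9.0 / 8.0
_X_LO, _X_HI = 8.0 / 9.0, 16.0 / 9.0


def in_wedge(tau_a: float, tau_x: float) -> bool:
    return _A_LO * tau_x < tau_a < _A_HI * tau_x


@dataclass
class ModelState:
    """All latent quantities of the joint model.

    ``x[sys]`` has shape (r+1, J_sys); row index = 1-based node id (row 0
    unused).  ``tau[sys]`` has length r+1 with entries for non-root nodes.
    """

    x: dict[str, np.ndarray]
    tau: dict[str, np.ndarray]
    mu: dict[str, float]
    nu: dict[str, float]

    def alpha(self, sys: str) -> float:
        return self.mu[sys] * self.nu[sys]

    def beta(self, sys: str) -> float:
        return (1.0 - self.mu[sys]) * self.nu[sys]


@dataclass
class ProposalScales:
    """Random-walk half-widths per parameter block (all strictly positive)."""

    x: dict[str, np.ndarray]  # per system, per node
    tau: np.ndarray  # per branch (shared by the A and X component proposals)
    mu: dict[str, float]
    log_nu: dict[str, float]


@dataclass
class PosteriorChain:
    """Thinned posterior draws plus bookkeeping needed downstream.

    ``tau[sys]`` is (T, B) over the ``branch_ids`` columns; ``x_mean[sys]``
    is the running posterior mean of every latent frequency (maintained
    during sampling instead of storing latent snapshots).
    """

    branch_ids: list[int]
    tau: dict[str, np.ndarray]
    mu: dict[str, np.ndarray]
    nu: dict[str, np.ndarray]
    deviance: np.ndarray
    x_mean: dict[str, np.ndarray]
    acceptance: dict[str, float]
    scales: ProposalScales
    config: RunConfig
    conditional: bool
    n_cond: dict[str, np.ndarray]
    wall_time: float = 0.0

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[0]

    def tau_means(self, sys: str) -> np.ndarray:
        return self.tau[sys].mean(axis=0)

    def xi_draws(self, branch_index: int) -> np.ndarray:
        """Per-draw ESR for the branch at position ``branch_index``."""
        ta = self.tau["A"][:, branch_index]
        tx = self.tau["X"][:, branch_index]
        return 2.0 - 9.0 * tx / (8.0 * ta)

    def to_dataframe(self, tree: PopulationTree | None = None) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for sys in SYSTEMS:
            for b, branch in enumerate(self.branch_ids):
                lab = tree.branch_label(branch) if tree else f"b{branch}"
                cols[f"tau_{sys}_{lab}"] = self.tau[sys][:, b]
        for sys in SYSTEMS:
            cols[f"mu_{sys}"] = self.mu[sys]
            cols[f"nu_{sys}"] = self.nu[sys]
        cols["deviance"] = self.deviance
        return pd.DataFrame(cols)


def _reflect01(v: np.ndarray) -> np.ndarray:
    """Fold values into [0, 1] by reflection at the boundaries."""
    v = np.mod(v, 2.0)
    return np.where(v > 1.0, 2.0 - v, v)


def _snap(v: np.ndarray, w: float) -> np.ndarray:
    """Map atom-strip values onto the absorbed states they represent.

    Frequencies in [0, w] / [1-w, 1] encode loss/fixation exactly; they are
    read as 0/1 wherever a frequency acts as an ancestral value or enters
    the binomial likelihood.  This keeps the sampled model consistent with
    the polymorphism conditioning, which assumes absorbed lineages are
    monomorphic.
    """
    return np.where(v <= w, 0.0, np.where(v >= 1.0 - w, 1.0, v))


def _binom_loglik(y: np.ndarray, n: np.ndarray, x: np.ndarray) -> np.ndarray:
    """y log x + (n-y) log(1-x) with exact-boundary conventions."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = y * np.log(x) + (n - y) * np.log1p(-x)
    t = np.where((x == 0.0) & (y == 0), 0.0, t)
    t = np.where((x == 1.0) & (y == n), 0.0, t)
    return np.where(np.isnan(t), -np.inf, t)


def _reflect_interval(v: float, lo: float, hi: float) -> float:
    """Fold a scalar into (lo, hi), iterating reflections as needed."""
    width = hi - lo
    y = np.mod(v - lo, 2.0 * width)
    if y > width:
        y = 2.0 * width - y
    out = lo + y
    # keep strictly interior (boundary hits are measure-zero but fatal)
    eps = 1e-12 * max(1.0, abs(hi))
    return min(max(out, lo + eps), hi - eps)


def _reflection_images(a: float, b: float, lo: float, hi: float,
                       s: float) -> int:
    """Number of reflection images of b inside the window (a-s, a+s).

    The density at b of a U(a-s, a+s) draw folded into (lo, hi) is this
    count divided by 2s.  It is needed explicitly because the support
    interval of each branch-length component depends on the other
    component's value, so forward and reverse proposal densities do not
    cancel in the Metropolis-Hastings ratio.
    """
    width = hi - lo
    rel = b - lo
    # images of b under the reflection group of (lo, hi): lo + 2k*width +/- rel
    k_lo = int(np.floor((a - s - lo) / (2.0 * width))) - 1
    k_hi = int(np.ceil((a + s - lo) / (2.0 * width))) + 1
    count = 0
    for k in range(k_lo, k_hi + 1):
        for img in (2.0 * k * width + rel, 2.0 * k * width - rel):
            if a - s < lo + img < a + s:
                count += 1
    return count


class GibbsSampler:
    """Stateful sampler bound to one dataset, tree and configuration.

    The public update methods mutate the current :class:`ModelState` in
    place and return acceptance information; :meth:`run` drives the full
    pilot -> burn-in -> sampling schedule.
    """

    def __init__(
        self,
        data: dict[str, AlleleCountMatrix],
        tree: PopulationTree,
        config: RunConfig,
    ):
        if set(data) != set(SYSTEMS):
            raise ValueError("data must map both systems 'A' and 'X'")
        self.data = data
        self.tree = tree
        self.config = config
        self.conditional = config.conditional
        self.rng = np.random.default_rng(config.seed)
        self.r = tree.n_nodes
        self.n_leaves = tree.n_leaves
        self.branch_ids = list(range(1, self.r))
        self.y = {s: data[s].y.astype(float) for s in SYSTEMS}
        self.n = {s: data[s].n.astype(float) for s in SYSTEMS}
        self.n_cond = {s: data[s].max_sample_sizes for s in SYSTEMS}
        # strip width representing the absorption atoms: 1/(2 n_max); the
        # fallback (no observed genes anywhere) only matters in prior runs
        self.atom_width = {
            s: 1.0 / (2.0 * n) if (n := int(self.n_cond[s].max())) > 0 else 0.005
            for s in SYSTEMS
        }
        self.logC = {
            s: float(
                np.sum(
                    gammaln(self.n[s] + 1)
                    - gammaln(self.y[s] + 1)
                    - gammaln(self.n[s] - self.y[s] + 1)
                )
            )
            for s in SYSTEMS
        }
        self.state = self._init_state()
        self.scales = self._init_scales()
        self.root_dist: dict[str, LineageCountDistribution] = {}
        self.logP: dict[str, np.ndarray] = {}
        self.lin_cache: dict[str, RootLineageCache] = {}
        if self.conditional:
            for s in SYSTEMS:
                self._refresh_conditioning(s)

    # ------------------------------------------------------------------ init

    def _init_state(self) -> ModelState:
        x = {}
        for s in SYSTEMS:
            J = self.data[s].n_snps
            arr = np.full((self.r + 1, J), 0.5)
            with np.errstate(invalid="ignore"):
                leaf = (self.y[s] + 0.5) / (self.n[s] + 1.0)
            arr[1 : self.n_leaves + 1] = np.clip(leaf, 0.02, 0.98)
            for node in self.tree.postorder():
                if self.tree.children[node]:
                    kids = list(self.tree.children[node])
                    arr[node] = np.clip(arr[kids].mean(axis=0), 0.02, 0.98)
            x[s] = arr
        tau = {
            "A": np.full(self.r + 1, 0.1),
            "X": np.full(self.r + 1, 0.1 / 0.75),
        }
        return ModelState(x=x, tau=tau, mu={s: 0.5 for s in SYSTEMS}, nu={s: 1.0 for s in SYSTEMS})

    def _init_scales(self) -> ProposalScales:
        return ProposalScales(
            x={s: np.full(self.r + 1, 0.1) for s in SYSTEMS},
            tau=np.full(self.r + 1, 0.02),
            mu={s: 0.1 for s in SYSTEMS},
            log_nu={s: 0.4 for s in SYSTEMS},
        )

    def _refresh_conditioning(self, sys: str) -> None:
        self.lin_cache[sys] = RootLineageCache(
            self.tree, self.state.tau[sys], self.n_cond[sys]
        )
        self.root_dist[sys] = self.lin_cache[sys].root_dist
        self.logP[sys] = log_prob_polymorphic(
            self.state.x[sys][self.r], self.root_dist[sys]
        )

    # --------------------------------------------------------------- updates

    def update_frequencies(self) -> dict[str, float]:
        """One vectorized Metropolis sweep over every node's frequencies."""
        rates = {}
        for s in SYSTEMS:
            x = self.state.x[s]
            tau = self.state.tau[s]
            w = self.atom_width[s]
            J = x.shape[1]
            for node in range(1, self.r + 1):
                cur = x[node]
                prop = _reflect01(
                    cur + self.scales.x[s][node] * self.rng.uniform(-1, 1, J)
                )
                np.clip(prop, 1e-12, 1.0 - 1e-12, out=prop)
                cur_s = _snap(cur, w)
                prop_s = _snap(prop, w)
                delta = np.zeros(J)
                if node <= self.n_leaves:
                    yv = self.y[s][node - 1]
                    nv = self.n[s][node - 1]
                    delta += _binom_loglik(yv, nv, prop_s) - _binom_loglik(
                        yv, nv, cur_s
                    )
                if node != self.r:
                    par = _snap(x[self.tree.parent[node]], w)
                    l_cur, l_prop = _logk_vec_pair_x(
                        par, cur, prop, float(tau[node]), w
                    )
                    delta += l_prop - l_cur
                else:
                    a, b = self.state.alpha(s), self.state.beta(s)
                    delta += (a - 1.0) * (np.log(prop) - np.log(cur)) + (
                        b - 1.0
                    ) * (np.log1p(-prop) - np.log1p(-cur))
                    if self.conditional:
                        lp_prop = log_prob_polymorphic(prop, self.root_dist[s])
                        delta += self.logP[s] - lp_prop
                for c in self.tree.children[node]:
                    l_cur, l_prop = _logk_vec_pair_p(
                        cur_s, prop_s, x[c], float(tau[c]), w
                    )
                    delta += l_prop - l_cur
                accept = np.log(self.rng.uniform(size=J)) < delta
                cur[accept] = prop[accept]
                if node == self.r and self.conditional:
                    self.logP[s][accept] = lp_prop[accept]
                rates[f"x_{s}_{node}"] = float(accept.mean()) if J else 0.3
        return rates

    def update_hyperparameters(self) -> dict[str, float]:
        """Metropolis updates of (mu, nu) for each system."""
        rates = {}
        for s in SYSTEMS:
            xr = self.state.x[s][self.r]
            lx = np.log(xr).sum()
            l1x = np.log1p(-xr).sum()
            J = xr.shape[0]
            mu, nu = self.state.mu[s], self.state.nu[s]

            def beta_ll(m: float, v: float) -> float:
                a, b = m * v, (1.0 - m) * v
                return (a - 1.0) * lx + (b - 1.0) * l1x - J * betaln(a, b)

            cur_ll = beta_ll(mu, nu)
            prop_mu = _reflect_interval(
                mu + self.scales.mu[s] * self.rng.uniform(-1, 1), 0.0, 1.0
            )
            delta = beta_ll(prop_mu, nu) - cur_ll
            acc_mu = np.log(self.rng.uniform()) < delta
            if acc_mu:
                self.state.mu[s] = mu = prop_mu
                cur_ll = beta_ll(mu, nu)
            prop_nu = nu * np.exp(
                self.scales.log_nu[s] * self.rng.uniform(-1, 1)
            )
            # exp(1) prior and log-scale Jacobian
            delta = (
                beta_ll(mu, prop_nu)
                - cur_ll
                - (prop_nu - nu)
                + (np.log(prop_nu) - np.log(nu))
            )
            acc_nu = np.log(self.rng.uniform()) < delta
            if acc_nu:
                self.state.nu[s] = prop_nu
            rates[f"mu_{s}"] = float(acc_mu)
            rates[f"nu_{s}"] = float(acc_nu)
        return rates

    def update_branch_pair(self, node: int) -> bool:
        """Joint reflected (tau_A, tau_X) update for the branch above ``node``.

        tau_A is proposed by reflection into the wedge section allowed by
        the current tau_X; tau_X then by reflection into the section
        allowed by the proposed tau_A; the pair is accepted together.  The
        ratio includes the drift kernels of branch ``node`` for both
        systems and, under conditioning, all per-site polymorphism terms
        (root lineage distributions recomputed under the proposal).
        """
        lo_b, hi_b = self.config.tau_bounds
        st = self.state
        ta, tx = float(st.tau["A"][node]), float(st.tau["X"][node])
        sc = float(self.scales.tau[node])
        lo_a = max(lo_b, _A_LO * tx)
        hi_a = min(hi_b, _A_HI * tx)
        prop_a = _reflect_interval(ta + sc * self.rng.uniform(-1, 1), lo_a, hi_a)
        lo_x = max(lo_b, _X_LO * prop_a)
        hi_x = min(hi_b, _X_HI * prop_a)
        prop_x = _reflect_interval(tx + sc * self.rng.uniform(-1, 1), lo_x, hi_x)

        # Hastings correction: the reflection intervals of each component
        # depend on the other component's value, so the proposal is not
        # symmetric between (ta, tx) and (prop_a, prop_x).
        rev_lo_a = max(lo_b, _A_LO * prop_x)
        rev_hi_a = min(hi_b, _A_HI * prop_x)
        rev_lo_x = max(lo_b, _X_LO * ta)
        rev_hi_x = min(hi_b, _X_HI * ta)
        if not (rev_lo_a < ta < rev_hi_a and rev_lo_x < tx < rev_hi_x):
            return False  # reverse move impossible: reject
        cr_a = _reflection_images(prop_a, ta, rev_lo_a, rev_hi_a, sc)
        cr_x = _reflection_images(prop_x, tx, rev_lo_x, rev_hi_x, sc)
        if cr_a == 0 or cr_x == 0:
            return False  # reverse proposal density is zero: reject
        cf_a = max(_reflection_images(ta, prop_a, lo_a, hi_a, sc), 1)
        cf_x = max(_reflection_images(tx, prop_x, lo_x, hi_x, sc), 1)
        delta = np.log(cr_a * cr_x) - np.log(cf_a * cf_x)
        new_rd: dict[str, LineageCountDistribution] = {}
        new_lp: dict[str, np.ndarray] = {}
        new_out: dict[str, dict] = {}
        for s, t_new in (("A", prop_a), ("X", prop_x)):
            x = st.x[s]
            w = self.atom_width[s]
            par = _snap(x[self.tree.parent[node]], w)
            t_old = float(st.tau[s][node])
            delta += float(
                np.sum(_logk_vec(par, x[node], t_new, w))
                - np.sum(_logk_vec(par, x[node], t_old, w))
            )
            if self.conditional:
                new_rd[s], new_out[s] = self.lin_cache[s].propose(node, t_new)
                new_lp[s] = log_prob_polymorphic(x[self.r], new_rd[s])
                delta += float(self.logP[s].sum() - new_lp[s].sum())
        accept = np.log(self.rng.uniform()) < delta
        if accept:
            st.tau["A"][node] = prop_a
            st.tau["X"][node] = prop_x
            if self.conditional:
                for s, t_new in (("A", prop_a), ("X", prop_x)):
                    self.lin_cache[s].commit(node, t_new, new_out[s], new_rd[s])
                    self.root_dist[s] = new_rd[s]
                    self.logP[s] = new_lp[s]
        return bool(accept)

    def iterate(self) -> dict[str, float]:
        """One full iteration of the fixed proposal schedule."""
        rates = self.update_frequencies()
        rates.update(self.update_hyperparameters())
        for node in self.branch_ids:
            rates[f"tau_{node}"] = float(self.update_branch_pair(node))
        return rates

    # ------------------------------------------------------------- deviance

    def deviance(self) -> float:
        """Conditional-likelihood deviance at the current state."""
        d = 0.0
        for s in SYSTEMS:
            x = _snap(self.state.x[s][1 : self.n_leaves + 1], self.atom_width[s])
            ll = float(np.sum(_binom_loglik(self.y[s], self.n[s], x))) + self.logC[s]
            if self.conditional:
                ll -= float(self.logP[s].sum())
            d += -2.0 * ll
        return d

    # ----------------------------------------------------------------- run

    def _run_phase(
        self, n_iter: int, label: str, collect: bool = False
    ) -> dict[str, float]:
        sums: dict[str, float] = {}
        for it in range(n_iter):
            rates = self.iterate()
            for k, v in rates.items():
                sums[k] = sums.get(k, 0.0) + v
            if (it + 1) % 1000 == 0:
                logger.info("%s: iteration %d/%d", label, it + 1, n_iter)
        return {k: v / n_iter for k, v in sums.items()}

    def pilot_tune(self) -> ProposalScales:
        """Adapt proposal scales with short pilot runs, then freeze them."""
        cfg = self.config
        lo, hi = cfg.target_acceptance
        factor = 1.25
        for pilot in range(cfg.n_pilot):
            rates = self._run_phase(cfg.pilot_length, f"pilot {pilot + 1}")
            for s in SYSTEMS:
                for node in range(1, self.r + 1):
                    r = rates[f"x_{s}_{node}"]
                    if r > hi:
                        self.scales.x[s][node] *= factor
                    elif r < lo:
                        self.scales.x[s][node] /= factor
                self.scales.x[s] = np.clip(self.scales.x[s], 1e-4, 1.0)
                if rates[f"mu_{s}"] > hi:
                    self.scales.mu[s] = min(self.scales.mu[s] * factor, 1.0)
                elif rates[f"mu_{s}"] < lo:
                    self.scales.mu[s] /= factor
                if rates[f"nu_{s}"] > hi:
                    self.scales.log_nu[s] = min(self.scales.log_nu[s] * factor, 5.0)
                elif rates[f"nu_{s}"] < lo:
                    self.scales.log_nu[s] /= factor
            for node in self.branch_ids:
                r = rates[f"tau_{node}"]
                if r > hi:
                    self.scales.tau[node] *= factor
                elif r < lo:
                    self.scales.tau[node] /= factor
            self.scales.tau = np.clip(self.scales.tau, 1e-6, 2.0)
            logger.info(
                "pilot %d/%d done; tau acceptance %s",
                pilot + 1,
                cfg.n_pilot,
                {n: round(rates[f"tau_{n}"], 2) for n in self.branch_ids},
            )
        return self.scales

    def run(self) -> PosteriorChain:
        """pilot_tune -> burn-in -> thinned sampling with deviance records."""
        t0 = time.time()
        cfg = self.config
        self.pilot_tune()
        self._run_phase(cfg.burnin, "burn-in")
        n_draws = cfg.chain_length // cfg.thin
        B = len(self.branch_ids)
        tau_draws = {s: np.empty((n_draws, B)) for s in SYSTEMS}
        mu_draws = {s: np.empty(n_draws) for s in SYSTEMS}
        nu_draws = {s: np.empty(n_draws) for s in SYSTEMS}
        dev = np.empty(n_draws)
        x_mean = {s: np.zeros_like(self.state.x[s]) for s in SYSTEMS}
        sums: dict[str, float] = {}
        d = 0
        for it in range(cfg.chain_length):
            rates = self.iterate()
            for k, v in rates.items():
                sums[k] = sums.get(k, 0.0) + v
            if (it + 1) % cfg.thin == 0:
                for s in SYSTEMS:
                    tau_draws[s][d] = self.state.tau[s][1 : self.r]
                    mu_draws[s][d] = self.state.mu[s]
                    nu_draws[s][d] = self.state.nu[s]
                    x_mean[s] += self.state.x[s]
                dev[d] = self.deviance()
                d += 1
            if (it + 1) % 1000 == 0:
                logger.info("sampling: iteration %d/%d", it + 1, cfg.chain_length)
        for s in SYSTEMS:
            x_mean[s] /= n_draws
        chain = PosteriorChain(
            branch_ids=self.branch_ids,
            tau=tau_draws,
            mu=mu_draws,
            nu=nu_draws,
            deviance=dev,
            x_mean=x_mean,
            acceptance={k: v / cfg.chain_length for k, v in sums.items()},
            scales=self.scales,
            config=cfg,
            conditional=self.conditional,
            n_cond=self.n_cond,
            wall_time=time.time() - t0,
        )
        logger.info("chain finished in %.1f s", chain.wall_time)
        return chain


def run_chain(
    data: dict[str, AlleleCountMatrix],
    tree: PopulationTree,
    config: RunConfig,
) -> PosteriorChain:
    """Fit the joint model; fully reproducible from ``config.seed``."""
    return GibbsSampler(data, tree, config).run()


def log_posterior(
    state: ModelState,
    data: dict[str, AlleleCountMatrix],
    tree: PopulationTree,
    config: RunConfig | None = None,
) -> float:
    """Full log posterior density (up to a constant) of a model state.

    Slow reference path used by tests and diagnostics; the sampler itself
    only ever forms ratios of the factors that an update touches.
    """
    cfg = config or RunConfig()
    lo_b, hi_b = cfg.tau_bounds
    r = tree.n_nodes
    total = 0.0
    for node in range(1, r):
        ta, tx = float(state.tau["A"][node]), float(state.tau["X"][node])
        if not (lo_b <= ta <= hi_b and lo_b <= tx <= hi_b and in_wedge(ta, tx)):
            return -np.inf
    for s in SYSTEMS:
        counts = data[s]
        x = state.x[s]
        y, n = counts.y.astype(float), counts.n.astype(float)
        n_max = int(counts.max_sample_sizes.max())
        w = 1.0 / (2.0 * n_max) if n_max > 0 else 0.005
        xl = _snap(x[1 : tree.n_leaves + 1], w)
        total += float(
            np.sum(
                gammaln(n + 1)
                - gammaln(y + 1)
                - gammaln(n - y + 1)
                + _binom_loglik(y, n, xl)
            )
        )
        for node in range(1, r):
            par = _snap(x[tree.parent[node]], w)
            total += float(
                np.sum(_logk_vec(par, x[node], float(state.tau[s][node]), w))
            )
        a, b = state.alpha(s), state.beta(s)
        xr = x[r]
        total += float(
            np.sum((a - 1.0) * np.log(xr) + (b - 1.0) * np.log1p(-xr))
            - xr.shape[0] * betaln(a, b)
        )
        if not (0.0 < state.mu[s] < 1.0) or state.nu[s] <= 0.0:
            return -np.inf
        total += -state.nu[s]  # exp(1) hyperprior on nu; mu flat
        if cfg.conditional:
            rd = root_lineage_distribution(
                tree, state.tau[s], counts.max_sample_sizes
            )
            total -= float(np.sum(log_prob_polymorphic(xr, rd)))
    return total


def deviance_at_means(
    chain: PosteriorChain,
    data: dict[str, AlleleCountMatrix],
    tree: PopulationTree,
) -> float:
    """Deviance evaluated at the posterior means of x and tau (for DIC)."""
    d = 0.0
    for si, s in enumerate(SYSTEMS):
        counts = data[s]
        y, n = counts.y.astype(float), counts.n.astype(float)
        xbar = np.clip(chain.x_mean[s][1 : tree.n_leaves + 1], 1e-12, 1 - 1e-12)
        ll = float(
            np.sum(
                gammaln(n + 1)
                - gammaln(y + 1)
                - gammaln(n - y + 1)
                + y * np.log(xbar)
                + (n - y) * np.log1p(-xbar)
            )
        )
        if chain.conditional:
            tau_bar = np.zeros(tree.n_nodes + 1)
            tau_bar[1 : tree.n_nodes] = chain.tau_means(s)
            rd = root_lineage_distribution(tree, tau_bar, chain.n_cond[s])
            xr_bar = chain.x_mean[s][tree.n_nodes]
            ll -= float(np.sum(log_prob_polymorphic(xr_bar, rd)))
        d += -2.0 * ll
    return d


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(message)s", "%H:%M:%S"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
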