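"""Synthetic data with sex-specific demography, in two modes.

*Forward mode* draws root frequencies from a beta distribution and
propagates them toward the leaves by binomial Wright-Fisher sampling with
the system-specific effective number of genes per branch - exactly the
generative model the inference assumes (drift kernel + beta root), so it
isolates the sampler from coalescent-model mismatch.

*Coalescent mode* mirrors the study design the method is meant for: gene
lineages of the sampled individuals are traced backward through a tree of
populations, each with its own female and male census sizes; pairs of
lineages within a population coalesce at the per-generation rate 1/(2Ne)
implied by Wright's sex-specific effective sizes

    Ne_A = 4 Nf Nm / (Nf + Nm),      Ne_X = 9 Nf Nm / (2 Nf + 4 Nm),

and migration moves lineages between two designated leaf populations at
the system-appropriate rate ((m_f + m_m)/2 for autosomes; an X lineage
sits in a female two-thirds of the time, so (2 m_f + m_m)/3 for X).  Loci
are strictly independent; no pedigree is built.  A locus is retained only
if its genealogy carries exactly one mutation (Poisson number given total
tree length), making every kept site bi-allelic and polymorphic in the
sample; ancestral/derived is mapped to reference/alternate uniformly at
random.

Ascertainment through a discovery panel ("ghost" individuals used for SNP
calling, then discarded) and pseudo-replicate subsampling complete the
study-design emulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from esrtree.datamodel import AlleleCountMatrix, PopulationTree

SYSTEMS = ("A", "X")


@dataclass(frozen=True)
class EffectiveSizes:
    """Wright's diploid-equivalent effective sizes for one census pair."""

    ne_a: float
    ne_x: float
    xi: float

    @property
    def ratio(self) -> float:
        return self.ne_x / self.ne_a


def effective_sizes(n_f: float, n_m: float) -> EffectiveSizes:
    """Autosomal and X-linked effective sizes from female/male censuses."""
    if n_f < 1 or n_m < 1:
        raise ValueError("census sizes must be >= 1")
    ne_a = 4.0 * n_f * n_m / (n_f + n_m)
    ne_x = 9.0 * n_f * n_m / (2.0 * n_f + 4.0 * n_m)
    return EffectiveSizes(ne_a=ne_a, ne_x=ne_x, xi=n_f / (n_f + n_m))


@dataclass
class BranchDemography:
    """Census sizes along one branch (population), possibly piecewise.

    ``events`` lists (time_in_generations_before_present, n_f, n_m):
    from that time backward (older), the new sizes apply.  Times must fall
    inside the branch's lifetime and be strictly increasing.
    """

    n_f: float
    n_m: float
    events: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_f < 1 or self.n_m < 1:
            raise ValueError("census sizes must be >= 1")
        times = [e[0] for e in self.events]
        if times != sorted(times) or len(set(times)) != len(times):
            raise ValueError("event times must be strictly increasing")

    def sizes_at(self, t: float) -> tuple[float, float]:
        """Census pair in force at backward time t."""
        nf, nm = self.n_f, self.n_m
        for when, f, m in self.events:
            if t >= when:
                nf, nm = f, m
        return nf, nm

    def segments(self, start: float, end: float):
        """(seg_start, seg_end, n_f, n_m) pieces covering [start, end)."""
        cuts = [start] + [e[0] for e in self.events if start < e[0] < end] + [end]
        for a, b in zip(cuts[:-1], cuts[1:]):
            nf, nm = self.sizes_at(a)
            yield a, b, nf, nm


@dataclass
class Migration:
    """Symmetric sex-specific migration between two leaf populations."""

    pop_a: str
    pop_b: str
    m_f: float
    m_m: float

    def __post_init__(self) -> None:
        for r in (self.m_f, self.m_m):
            if not (0.0 <= r <= 0.5):
                raise ValueError("migration rates must lie in [0, 0.5]")

    def rate(self, sys: str) -> float:
        if sys == "A":
            return 0.5 * (self.m_f + self.m_m)
        return (2.0 * self.m_f + self.m_m) / 3.0


@dataclass
class DemographyConfig:
    """Full specification of a simulated sex-specific history.

    ``split_times[i]`` (generations before present) is when the children
    of internal node i merge into it; ``branches[i]`` gives the censuses
    of the population along the branch above node i (the root entry
    describes the ancestral population, which extends indefinitely into
    the past).  ``samples_f``/``samples_m`` are diploid individuals
    sampled per leaf: a female carries 2 autosomal + 2 X genes, a male
    2 autosomal + 1 X gene.
    """

    tree: PopulationTree
    split_times: dict[int, float]
    branches: dict[int, BranchDemography]
    mutation_rate: float
    samples_f: dict[int, int]
    samples_m: dict[int, int]
    n_snps: dict[str, int]
    migration: Migration | None = None

    def __post_init__(self) -> None:
        tree = self.tree
        for i in range(tree.n_leaves + 1, tree.n_nodes + 1):
            if i not in self.split_times:
                raise ValueError(f"missing split time for internal node {i}")
        for i in range(1, tree.n_nodes + 1):
            if i not in self.branches:
                raise ValueError(f"missing demography for node {i}")
        for node in range(tree.n_leaves + 1, tree.n_nodes):
            if self.split_times[node] >= self.split_times[tree.parent[node]]:
                raise ValueError("split times must increase root-ward")
        if self.mutation_rate <= 0:
            raise ValueError("mutation rate must be positive")
        if self.migration is not None:
            labs = set(self.tree.leaf_labels)
            if {self.migration.pop_a, self.migration.pop_b} - labs:
                raise ValueError("migration populations must be leaves")

    # ------------------------------------------------------------ intervals

    def node_start(self, node: int) -> float:
        return 0.0 if node <= self.tree.n_leaves else self.split_times[node]

    def node_end(self, node: int) -> float:
        if node == self.tree.root:
            return np.inf
        return self.split_times[self.tree.parent[node]]

    def sample_genes(self, leaf: int, sys: str) -> int:
        f = self.samples_f.get(leaf, 0)
        m = self.samples_m.get(leaf, 0)
        return 2 * (f + m) if sys == "A" else 2 * f + m

    # ---------------------------------------------------------------- truth

    def true_tau(self, node: int, sys: str) -> float:
        """Expected drift time of the branch above ``node``.

        Sum of seg_duration/(2 Ne) over the branch's piecewise-constant
        census segments, i.e. duration over twice the harmonic-mean Ne.
        """
        if node == self.tree.root:
            raise ValueError("the root has no branch above it")
        tau = 0.0
        for a, b, nf, nm in self.branches[node].segments(
            self.node_start(node), self.node_end(node)
        ):
            ne = effective_sizes(nf, nm)
            tau += (b - a) / (2.0 * (ne.ne_a if sys == "A" else ne.ne_x))
        return tau

    def truth(self) -> dict:
        """Per-branch true drift times and ESR (drives recovery tests)."""
        out = {}
        for node in range(1, self.tree.n_nodes):
            ta = self.true_tau(node, "A")
            tx = self.true_tau(node, "X")
            out[self.tree.branch_label(node)] = {
                "branch": node,
                "tau_A": ta,
                "tau_X": tx,
                "xi": 2.0 - 9.0 * tx / (8.0 * ta),
            }
        return out


def balanced_demography(
    tree: PopulationTree,
    split_times: dict[int, float],
    n_f: float,
    n_m: float,
    root_n_f: float,
    root_n_m: float,
    mutation_rate: float,
    samples_f: int,
    n_snps: int,
) -> DemographyConfig:
    """Convenience constructor: same censuses on every non-root branch."""
    branches = {
        i: BranchDemography(n_f=n_f, n_m=n_m) for i in range(1, tree.n_nodes)
    }
    branches[tree.root] = BranchDemography(n_f=root_n_f, n_m=root_n_m)
    return DemographyConfig(
        tree=tree,
        split_times=split_times,
        branches=branches,
        mutation_rate=mutation_rate,
        samples_f={i: samples_f for i in range(1, tree.n_leaves + 1)},
        samples_m={i: 0 for i in range(1, tree.n_leaves + 1)},
        n_snps={"A": n_snps, "X": n_snps},
    )


# ---------------------------------------------------------------- forward


def _wf_propagate(
    x: np.ndarray, two_ne: int, generations: int, rng: np.random.Generator
) -> np.ndarray:
    for _ in range(generations):
        x = rng.binomial(two_ne, x) / two_ne
    return x


def simulate_forward(
    config: DemographyConfig,
    root_beta: tuple[float, float] = (1.0, 1.0),
    rng: np.random.Generator | int | None = None,
    max_rounds: int = 200,
) -> dict[str, AlleleCountMatrix]:
    """Model-faithful generator: beta root + per-branch binomial drift.

    Per locus and system, a root frequency is drawn from
    Beta(``root_beta``), propagated along every branch by per-generation
    binomial resampling of 2*Ne(sys) genes, and leaf counts are binomial
    draws given the leaf frequencies.  Loci monomorphic in the pooled
    sample are discarded and redrawn until the requested number of SNPs
    is reached (the polymorphism conditioning of the inference model
    mirrors exactly this rejection).
    """
    rng = np.random.default_rng(rng)
    tree = config.tree
    out = {}
    for sys in SYSTEMS:
        target = config.n_snps[sys]
        n_genes = np.array(
            [config.sample_genes(i, sys) for i in range(1, tree.n_leaves + 1)]
        )
        kept_y: list[np.ndarray] = [np.zeros((tree.n_leaves, 0), dtype=np.int64)]
        kept = 0
        rounds = 0
        while kept < target:
            rounds += 1
            if rounds > max_rounds:
                raise RuntimeError(
                    f"could not collect {target} polymorphic loci for system "
                    f"{sys}: root distribution may be degenerate"
                )
            batch = max(256, int(1.5 * (target - kept)))
            x = {tree.root: rng.beta(root_beta[0], root_beta[1], size=batch)}
            for node in reversed(tree.postorder()):
                if node == tree.root:
                    continue
                xv = x[tree.parent[node]]
                start, end = config.node_start(node), config.node_end(node)
                # chronological (oldest-first) order for forward propagation
                for a, b, nf, nm in reversed(
                    list(config.branches[node].segments(start, end))
                ):
                    ne = effective_sizes(nf, nm)
                    two_ne = max(2, int(round(2 * (ne.ne_a if sys == "A" else ne.ne_x))))
                    xv = _wf_propagate(xv, two_ne, int(round(b - a)), rng)
                x[node] = xv
            y = np.vstack(
                [
                    rng.binomial(n_genes[i - 1], x[i])
                    for i in range(1, tree.n_leaves + 1)
                ]
            )
            tot = y.sum(axis=0)
            poly = (tot > 0) & (tot < n_genes.sum())
            kept_y.append(y[:, poly])
            kept += int(poly.sum())
        y = np.hstack(kept_y)[:, :target]
        n = np.tile(n_genes[:, None], (1, target))
        out[sys] = AlleleCountMatrix(
            system=sys,
            snp_ids=[f"{sys.lower()}snp{j + 1}" for j in range(target)],
            y=y,
            n=n,
        )
    return out


# -------------------------------------------------------------- coalescent


class _Genealogy:
    """One locus genealogy built backward in time (continuous-time rates)."""

    __slots__ = ("parent", "children", "birth", "length", "n_samples")

    def __init__(self, n_samples: int):
        self.n_samples = n_samples
        self.parent = [-1] * n_samples
        self.children: list[tuple[int, int] | None] = [None] * n_samples
        self.birth = [0.0] * n_samples
        self.length = 0.0

    def coalesce(self, a: int, b: int, t: float) -> int:
        node = len(self.parent)
        self.parent.append(-1)
        self.children.append((a, b))
        self.birth.append(t)
        self.parent[a] = node
        self.parent[b] = node
        self.length += (t - self.birth[a]) + (t - self.birth[b])
        return node

    def edge_durations(self, t_mrca: float) -> np.ndarray:
        """Duration of the edge above every node except the MRCA."""
        n = len(self.parent)
        out = np.zeros(n)
        for i in range(n - 1):
            out[i] = self.birth[self.parent[i]] - self.birth[i]
        return out

    def descendants(self, node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n_samples:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out


def _simulate_locus(
    config: DemographyConfig,
    sys: str,
    rng: np.random.Generator,
) -> tuple[_Genealogy, np.ndarray, float]:
    """Trace one locus to its MRCA; returns genealogy, sample pops, t_mrca."""
    tree = config.tree
    lineages: dict[int, list[int]] = {}
    sample_pop = []
    gen = None
    idx = 0
    for leaf in range(1, tree.n_leaves + 1):
        k = config.sample_genes(leaf, sys)
        lineages[leaf] = list(range(idx, idx + k))
        sample_pop.extend([leaf] * k)
        idx += k
    gen = _Genealogy(idx)

    mig = config.migration
    mig_pair: tuple[int, int] | None = None
    mig_rate = 0.0
    if mig is not None:
        ia = tree.leaf_labels.index(mig.pop_a) + 1
        ib = tree.leaf_labels.index(mig.pop_b) + 1
        mig_pair = (ia, ib)
        mig_rate = mig.rate(sys)

    # structural boundaries: population merges and size-change events
    boundaries = sorted(
        {config.split_times[i] for i in range(tree.n_leaves + 1, tree.n_nodes + 1)}
        | {
            e[0]
            for i in range(1, tree.n_nodes + 1)
            for e in config.branches[i].events
        }
    )
    def _two_ne(pop: int, t: float) -> float:
        nf, nm = config.branches[pop].sizes_at(t)
        ne = effective_sizes(nf, nm)
        return 2.0 * (ne.ne_a if sys == "A" else ne.ne_x)

    t = 0.0
    b_idx = 0
    inv_two_ne = {p: 1.0 / _two_ne(p, t) for p in lineages}
    n_act = sum(len(v) for v in lineages.values())
    expo = rng.exponential
    rand = rng.random
    while n_act > 1:
        t_next = boundaries[b_idx] if b_idx < len(boundaries) else np.inf
        pops = list(lineages)
        lam = 0.0
        rates = []
        for p in pops:
            k = len(lineages[p])
            r = 0.5 * k * (k - 1) * inv_two_ne[p]
            rates.append(r)
            lam += r
        mig_active = (
            mig_rate > 0.0
            and mig_pair[0] in lineages
            and mig_pair[1] in lineages
        )
        if mig_active:
            r0 = len(lineages[mig_pair[0]]) * mig_rate
            r1 = len(lineages[mig_pair[1]]) * mig_rate
            rates.append(r0)
            rates.append(r1)
            lam += r0 + r1
        dt = expo() / lam if lam > 0.0 else np.inf
        if t + dt >= t_next:
            # structural boundary: merge populations splitting here and
            # refresh piecewise census sizes
            t = t_next
            b_idx += 1
            for node in range(tree.n_leaves + 1, tree.n_nodes + 1):
                if config.split_times[node] == t:
                    merged = []
                    for c in tree.children[node]:
                        merged.extend(lineages.pop(c, []))
                        inv_two_ne.pop(c, None)
                    lineages.setdefault(node, []).extend(merged)
            inv_two_ne = {p: 1.0 / _two_ne(p, t) for p in lineages}
            continue
        t += dt
        u = rand() * lam
        choice = 0
        acc = rates[0]
        while acc < u and choice < len(rates) - 1:
            choice += 1
            acc += rates[choice]
        if choice < len(pops):
            pool = lineages[pops[choice]]
            k = len(pool)
            i = int(rand() * k)
            j = int(rand() * (k - 1))
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            node = gen.coalesce(a, b, t)
            # swap-remove both, append the parent lineage
            hi, lo = (i, j) if i > j else (j, i)
            pool[hi] = pool[-1]
            pool.pop()
            pool[lo] = pool[-1]
            pool.pop()
            pool.append(node)
            n_act -= 1
        else:
            src = mig_pair[0] if choice == len(pops) else mig_pair[1]
            dst = mig_pair[1] if choice == len(pops) else mig_pair[0]
            pool = lineages[src]
            i = int(rand() * len(pool))
            v = pool[i]
            pool[i] = pool[-1]
            pool.pop()
            lineages[dst].append(v)
    return gen, np.asarray(sample_pop), t


def simulate_coalescent(
    config: DemographyConfig,
    rng: np.random.Generator | int | None = None,
    max_attempts_factor: int = 500,
) -> dict[str, AlleleCountMatrix]:
    """Backward-in-time generator with sex-specific demography.

    Loci are simulated independently until ``config.n_snps[sys]`` genealogies
    carrying exactly one mutation have been collected per system (the number
    of mutations is Poisson with mean mutation_rate * total tree length in
    generations; multi-mutation and mutation-free genealogies are
    discarded).  The single mutation is placed uniformly on the genealogy
    and its carriers define the derived allele; derived/ancestral is mapped
    to reference/alternate with probability 1/2 each.
    """
    rng = np.random.default_rng(rng)
    tree = config.tree
    out = {}
    for sys in SYSTEMS:
        target = config.n_snps[sys]
        n_genes = np.array(
            [config.sample_genes(i, sys) for i in range(1, tree.n_leaves + 1)]
        )
        ys: list[np.ndarray] = []
        if target == 0:
            out[sys] = AlleleCountMatrix(
                system=sys, snp_ids=[],
                y=np.zeros((tree.n_leaves, 0), dtype=np.int64),
                n=np.zeros((tree.n_leaves, 0), dtype=np.int64),
            )
            continue
        attempts = 0
        while len(ys) < target:
            attempts += 1
            if attempts > max_attempts_factor * target:
                raise RuntimeError(
                    f"single-mutation rejection not converging for system {sys}"
                )
            gen, sample_pop, _ = _simulate_locus(config, sys, rng)
            n_mut = rng.poisson(config.mutation_rate * gen.length)
            if n_mut != 1:
                continue
            durations = gen.edge_durations(0.0)
            edge = rng.choice(durations.shape[0], p=durations / durations.sum())
            carriers = gen.descendants(int(edge))
            y_der = np.bincount(
                sample_pop[carriers], minlength=tree.n_leaves + 1
            )[1:]
            if rng.uniform() < 0.5:
                ys.append(n_genes - y_der)
            else:
                ys.append(y_der)
        y = np.array(ys).T[:, :target]
        n = np.tile(n_genes[:, None], (1, target))
        out[sys] = AlleleCountMatrix(
            system=sys,
            snp_ids=[f"{sys.lower()}snp{j + 1}" for j in range(target)],
            y=y,
            n=n,
        )
    return out


# ------------------------------------------------------------ ascertainment


def apply_ascertainment(
    counts: dict[str, AlleleCountMatrix],
    panel_ghosts: dict[int, int],
    rng: np.random.Generator | int | None = None,
) -> dict[str, AlleleCountMatrix]:
    """Discovery-panel ascertainment with ghost (female) individuals.

    ``panel_ghosts`` maps 1-based population indices to the number of
    diploid female ghost individuals contributed to the discovery panel.
    For each site, ghost gene counts are drawn hypergeometrically from the
    population's allele counts (genes within a population are
    exchangeable); only sites polymorphic among the pooled ghost genes are
    retained, with the ghost genes removed from the returned counts.
    """
    if not panel_ghosts:
        raise ValueError("empty discovery panel")
    if all(g == 0 for g in panel_ghosts.values()):
        return {s: acm for s, acm in counts.items()}  # no ghosts: identity
    rng = np.random.default_rng(rng)
    out = {}
    for sys, acm in counts.items():
        ghost_genes = np.zeros(acm.n_pops, dtype=np.int64)
        for pop, g in panel_ghosts.items():
            ghost_genes[pop - 1] = 2 * g  # female ghosts: 2 genes both systems
        if np.any(ghost_genes[:, None] > acm.n):
            raise ValueError("more ghost genes than sampled genes")
        ghost_y = np.zeros_like(acm.y)
        for i in range(acm.n_pops):
            if ghost_genes[i] > 0:
                ghost_y[i] = rng.hypergeometric(
                    acm.y[i], acm.n[i] - acm.y[i], ghost_genes[i]
                )
        tot_gy = ghost_y.sum(axis=0)
        tot_gn = ghost_genes.sum()
        keep = (tot_gy > 0) & (tot_gy < tot_gn)
        y_new = (acm.y - ghost_y)[:, keep]
        n_new = (acm.n - ghost_genes[:, None])[:, keep]
        out[sys] = AlleleCountMatrix(
            system=sys,
            snp_ids=[s for s, k in zip(acm.snp_ids, keep) if k],
            y=y_new,
            n=n_new,
        )
    return out


def subsample_replicates(
    counts: dict[str, AlleleCountMatrix],
    n_snps_per_system: int,
    n_replicates: int,
    seed: int | None = None,
) -> list[dict[str, AlleleCountMatrix]]:
    """Pseudo-replicated subsets: uniform draws without replacement.

    Sampling is independent across replicates (the same SNP may appear in
    several replicates), reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    for sys, acm in counts.items():
        if n_snps_per_system > acm.n_snps:
            raise ValueError(
                f"requested {n_snps_per_system} SNPs but system {sys} has "
                f"only {acm.n_snps}"
            )
    reps = []
    for _ in range(n_replicates):
        rep = {}
        for sys, acm in counts.items():
            idx = np.sort(
                rng.choice(acm.n_snps, size=n_snps_per_system, replace=False)
            )
            rep[sys] = AlleleCountMatrix(
                system=sys,
                snp_ids=[acm.snp_ids[j] for j in idx],
                y=acm.y[:, idx],
                n=acm.n[:, idx],
            )
        reps.append(rep)
    return reps
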