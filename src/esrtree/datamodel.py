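"""Domain types: population trees, allele-count matrices, run configuration.

Node indexing convention: sampled populations (leaves) carry ids 1..I in
count-table column order, internal nodes carry ids I+1..r in post-order, and
r is the root.  This fixed convention makes every downstream index (branch
summaries, chain columns) reproducible across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input tree or count table violates a model invariant."""


@dataclass(frozen=True)
class PopulationTree:
    """Rooted, possibly multifurcating topology over I sampled populations.

    Attributes
    ----------
    leaf_labels:
        Population names for leaves 1..I (``leaf_labels[0]`` is node 1).
    n_nodes:
        Total number of nodes r (leaves + internal nodes incl. root).
    parent:
        ``parent[i]`` is the ancestor a(i) of node i, for i in 1..r-1 using
        1-based ids; ``parent[0]`` is unused and ``parent[r]`` is 0.
    children:
        ``children[i]`` is the tuple of child ids of node i (empty for leaves).
    """

    leaf_labels: tuple[str, ...]
    n_nodes: int
    parent: tuple[int, ...]
    children: tuple[tuple[int, ...], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def root(self) -> int:
        return self.n_nodes

    @property
    def n_branches(self) -> int:
        """Number of non-root branches (branch i leads to node i)."""
        return self.n_nodes - 1

    def postorder(self) -> list[int]:
        """Node ids, children always before parents (leaves first by id)."""
        order: list[int] = []
        seen: set[int] = set()

        def visit(node: int) -> None:
            for c in self.children[node]:
                visit(c)
            order.append(node)
            seen.add(node)

        visit(self.root)
        return order

    def branch_label(self, i: int) -> str:
        if i <= self.n_leaves:
            return self.leaf_labels[i - 1]
        return f"internal_{i}"

    def to_newick(self) -> str:
        def min_leaf(node: int) -> int:
            if not self.children[node]:
                return node
            return min(min_leaf(c) for c in self.children[node])

        def render(node: int) -> str:
            if not self.children[node]:
                return self.leaf_labels[node - 1]
            kids = sorted(self.children[node], key=min_leaf)
            return "(" + ",".join(render(c) for c in kids) + ")"

        return render(self.root) + ";"


def parse_tree(newick: str, leaf_order: list[str] | None = None) -> PopulationTree:
    """Parse a rooted newick topology into a :class:`PopulationTree`.

    Branch lengths in the newick string are ignored: the model estimates
    drift times itself.  ``leaf_order`` (typically count-table column order)
    fixes the 1..I leaf numbering; by default the left-to-right newick order
    is used.

    Raises
    ------
    ValidationError
        on duplicate leaf labels, single-child nodes (including a root with
        one child, as produced by rooting an unrooted tree improperly), or
        a ``leaf_order`` that does not match the leaf label set.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        if "Duplicate taxon" in str(exc) or "same taxa" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise ValidationError(f"could not parse newick: {exc}") from exc
    dnodes = list(tree.preorder_node_iter())
    labels = [
        nd.taxon.label for nd in dnodes if nd.is_leaf() and nd.taxon is not None
    ]
    if any(nd.is_leaf() and nd.taxon is None for nd in dnodes):
        raise ValidationError("tree contains an unlabeled leaf")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate leaf labels: {dupes}")
    for nd in dnodes:
        if not nd.is_leaf() and len(nd.child_nodes()) < 2:
            raise ValidationError(
                "internal node with a single child (is the input rooted "
                "through a unary root?)"
            )

    if leaf_order is None:
        leaf_order = labels
    elif set(leaf_order) != set(labels):
        missing = sorted(set(labels) - set(leaf_order))
        extra = sorted(set(leaf_order) - set(labels))
        raise ValidationError(
            f"leaf labels do not match populations: tree-only={missing}, "
            f"table-only={extra}"
        )

    n_leaves = len(leaf_order)
    leaf_id = {lab: i + 1 for i, lab in enumerate(leaf_order)}
    ids: dict[int, int] = {}
    next_internal = n_leaves + 1
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ids[id(nd)] = leaf_id[nd.taxon.label]
        else:
            ids[id(nd)] = next_internal
            next_internal += 1
    n_nodes = next_internal - 1

    parent = [0] * (n_nodes + 1)
    children: list[list[int]] = [[] for _ in range(n_nodes + 1)]
    for nd in tree.postorder_node_iter():
        if nd.parent_node is not None:
            parent[ids[id(nd)]] = ids[id(nd.parent_node)]
            children[ids[id(nd.parent_node)]].append(ids[id(nd)])
    return PopulationTree(
        leaf_labels=tuple(leaf_order),
        n_nodes=n_nodes,
        parent=tuple(parent),
        children=tuple(tuple(sorted(c)) for c in children),
    )


@dataclass
class AlleleCountMatrix:
    """Per-SNP, per-population allele counts for one genetic system.

    ``y[i, j]`` is the reference-allele count and ``n[i, j]`` the total number
    of sampled genes for population i (row order = tree leaf order 1..I) at
    SNP j.  ``n[i, j] == 0`` encodes a population with no data at that site.
    """

    system: str
    snp_ids: list[str]
    y: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.system not in ("A", "X"):
            raise ValidationError(f"unknown genetic system {self.system!r}")
        if self.y.shape != self.n.shape or self.y.ndim != 2:
            raise ValidationError("y and n must be matching [I x J] matrices")
        if len(self.snp_ids) != self.y.shape[1]:
            raise ValidationError("snp_ids length must equal the number of columns")

    @property
    def n_pops(self) -> int:
        return self.y.shape[0]

    @property
    def n_snps(self) -> int:
        return self.y.shape[1]

    @property
    def max_sample_sizes(self) -> np.ndarray:
        """Per-population maximum gene count across sites (conditioning n)."""
        if self.n_snps == 0:
            return np.zeros(self.n_pops, dtype=np.int64)
        return self.n.max(axis=1)


def validate_counts(
    counts: AlleleCountMatrix,
    tree: PopulationTree | None = None,
) -> dict:
    """Check count-table invariants; raise :class:`ValidationError` on failure.

    Returns a report with the SNP count, per-population maximum sample sizes
    and the number of sites failing the pooled-polymorphism requirement
    0 < sum_i y_ij < sum_i n_ij.
    """
    y, n = counts.y, counts.n
    if tree is not None and counts.n_pops != tree.n_leaves:
        raise ValidationError(
            f"count table has {counts.n_pops} populations but the tree has "
            f"{tree.n_leaves} leaves"
        )
    if (n < 0).any():
        raise ValidationError("negative sample size")
    bad = np.where((y < 0) | (y > n))
    if bad[0].size:
        i, j = bad[0][0], bad[1][0]
        raise ValidationError(
            f"y outside [0, n] at SNP {counts.snp_ids[j]!r}, population row {i + 1}"
        )
    tot_y = y.sum(axis=0)
    tot_n = n.sum(axis=0)
    mono = np.where((tot_y == 0) | (tot_y == tot_n))[0]
    if mono.size:
        names = [counts.snp_ids[j] for j in mono[:5]]
        raise ValidationError(
            f"{mono.size} site(s) monomorphic in the pooled sample "
            f"(first: {names}); the model conditions on polymorphism"
        )
    return {
        "system": counts.system,
        "n_snps": counts.n_snps,
        "max_sample_sizes": counts.max_sample_sizes.tolist(),
        "n_monomorphic": int(mono.size),
    }


def read_counts(path_or_buf, system: str) -> AlleleCountMatrix:
    """Read a count TSV (columns ``snp_id``, ``<pop>_y``, ``<pop>_n``, ...)."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"snp_id": str})
    if "snp_id" not in df.columns:
        raise ValidationError("count table must have a 'snp_id' column")
    pops = []
    for col in df.columns:
        if col.endswith("_y"):
            pop = col[:-2]
            if f"{pop}_n" not in df.columns:
                raise ValidationError(f"missing column {pop}_n")
            pops.append(pop)
    if not pops:
        raise ValidationError("no <pop>_y / <pop>_n column pairs found")
    y = np.vstack([df[f"{p}_y"].to_numpy(dtype=np.int64) for p in pops])
    n = np.vstack([df[f"{p}_n"].to_numpy(dtype=np.int64) for p in pops])
    return AlleleCountMatrix(
        system=system, snp_ids=df["snp_id"].tolist(), y=y, n=n
    )


def write_counts(counts: AlleleCountMatrix, path_or_buf) -> None:
    """Write a count table in the TSV layout read by :func:`read_counts`."""
    pops = [f"P{i + 1}" for i in range(counts.n_pops)]
    data: dict[str, object] = {"snp_id": counts.snp_ids}
    for i, p in enumerate(pops):
        data[f"{p}_y"] = counts.y[i]
        data[f"{p}_n"] = counts.n[i]
    pd.DataFrame(data).to_csv(path_or_buf, sep="\t", index=False)


def counts_to_tsv(counts: AlleleCountMatrix) -> str:
    buf = io.StringIO()
    write_counts(counts, buf)
    return buf.getvalue()


@dataclass
class RunConfig:
    """MCMC run configuration.

    Defaults follow the method's standard settings: 20 pilot runs of 500
    iterations to tune proposal scales into the 0.25-0.40 acceptance band,
    a 10,000-iteration burn-in, 20,000 sampling iterations thinned every 20,
    and drift times bounded in [1e-4, 10].
    """

    n_pilot: int = 20
    pilot_length: int = 500
    burnin: int = 10_000
    chain_length: int = 20_000
    thin: int = 20
    seed: int = 1
    target_acceptance: tuple[float, float] = (0.25, 0.40)
    tau_bounds: tuple[float, float] = (1e-4, 10.0)
    conditional: bool = True

    def __post_init__(self) -> None:
        for name in ("n_pilot", "pilot_length", "burnin", "chain_length", "thin"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.target_acceptance
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("target_acceptance must be within (0, 1)")
        if self.chain_length % self.thin != 0:
            raise ValidationError("thin must divide chain_length")
        lo, hi = self.tau_bounds
        if not (0.0 < lo < hi):
            raise ValidationError("invalid tau_bounds")
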