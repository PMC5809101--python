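"""Canonical simulation scenarios for validating ESR inference.

Each constructor returns a :class:`~esrtree.simulate.DemographyConfig`
describing one of the standard evaluation designs: tree-shaped divergence
from a large ancestral population (50,000 females and 50,000 males, so
that polymorphism is overwhelmingly ancestral), 50 diploid females sampled
per population (100 genes for both genetic systems), and 5,000 SNPs per
system by default.  ``n_snps`` can be lowered for quicker, reduced-scale
replicates; everything else is part of the study design.

The three-population histories use topology ((P1,P2),P3) with splits at
200 and 400 generations and mutation rate 5e-7; the four-population
histories use ((P1,P2),(P3,P4)) and mutation rate 1.5e-7.
"""

from __future__ import annotations

from esrtree.datamodel import parse_tree
from esrtree.simulate import BranchDemography, DemographyConfig, Migration

ROOT = BranchDemography(50_000, 50_000)


def _three_pop(branches: dict[int, BranchDemography], n_snps: int,
               mutation_rate: float = 5e-7,
               splits: tuple[float, float] = (200.0, 400.0),
               migration: Migration | None = None) -> DemographyConfig:
    tree = parse_tree("((P1,P2),P3);")
    return DemographyConfig(
        tree=tree,
        split_times={4: splits[0], 5: splits[1]},
        branches=branches,
        mutation_rate=mutation_rate,
        samples_f={1: 50, 2: 50, 3: 50},
        samples_m={1: 0, 2: 0, 3: 0},
        n_snps={"A": n_snps, "X": n_snps},
        migration=migration,
    )


def _four_pop(branches: dict[int, BranchDemography], n_snps: int,
              splits: tuple[float, float],
              migration: Migration | None = None) -> DemographyConfig:
    tree = parse_tree("((P1,P2),(P3,P4));")
    return DemographyConfig(
        tree=tree,
        split_times={5: splits[0], 6: splits[0], 7: splits[1]},
        branches=branches,
        mutation_rate=1.5e-7,
        samples_f={i: 50 for i in range(1, 5)},
        samples_m={i: 0 for i in range(1, 5)},
        n_snps={"A": n_snps, "X": n_snps},
        migration=migration,
    )


def three_pop_biased(n_snps: int = 5000,
                     biased_branch: int = 2) -> DemographyConfig:
    """Three populations, one branch with 250 females / 750 males (xi=0.25).

    All other branches have 500 females and 500 males (xi = 0.5).
    """
    branches = {i: BranchDemography(500, 500) for i in range(1, 5)}
    branches[biased_branch] = BranchDemography(250, 750)
    branches[5] = ROOT
    return _three_pop(branches, n_snps)


def three_pop_balanced(n_snps: int = 5000) -> DemographyConfig:
    """Three populations, balanced sex ratio everywhere."""
    branches = {i: BranchDemography(500, 500) for i in range(1, 5)}
    branches[5] = ROOT
    return _three_pop(branches, n_snps)


def four_pop_external_bias(n_snps: int = 5000) -> DemographyConfig:
    """Four populations with strongly biased ESR on every external branch.

    Branch censuses (females/males): P1 1,000/9,000 (xi=0.1), P2
    2,000/8,000 (0.2), P3 9,000/1,000 (0.9), P4 8,000/2,000 (0.8);
    internal branches 5,000/5,000; splits at 1,000 and 3,000 generations.
    """
    branches = {
        1: BranchDemography(1_000, 9_000),
        2: BranchDemography(2_000, 8_000),
        3: BranchDemography(9_000, 1_000),
        4: BranchDemography(8_000, 2_000),
        5: BranchDemography(5_000, 5_000),
        6: BranchDemography(5_000, 5_000),
        7: ROOT,
    }
    return _four_pop(branches, n_snps, splits=(1_000.0, 3_000.0))


def four_pop_control(n_snps: int = 5000,
                     migration: Migration | None = None) -> DemographyConfig:
    """Four populations, 5,000/5,000 on every branch, splits 2,000/4,000.

    The balanced "control" design; pass a :class:`Migration` to add gene
    flow between P1 and P2 (rates 0.00025 give 4*N*m = 5).
    """
    branches = {i: BranchDemography(5_000, 5_000) for i in range(1, 7)}
    branches[7] = ROOT
    return _four_pop(branches, n_snps, splits=(2_000.0, 4_000.0),
                     migration=migration)


def four_pop_size_change(n_snps: int = 5000, fold: float = 5.0) -> DemographyConfig:
    """Control design plus an instantaneous size change 400 generations ago.

    Branch P1 grew ``fold``-fold (it was smaller before 400 generations
    ago) and branch P4 went through a ``fold``-fold bottleneck (it was
    larger before).  Expected drift times use the harmonic-mean census
    along each branch.
    """
    branches = {i: BranchDemography(5_000, 5_000) for i in range(1, 7)}
    branches[1] = BranchDemography(
        5_000, 5_000, events=[(400.0, 5_000 / fold, 5_000 / fold)]
    )
    branches[4] = BranchDemography(
        5_000, 5_000, events=[(400.0, 5_000 * fold, 5_000 * fold)]
    )
    branches[7] = ROOT
    return _four_pop(branches, n_snps, splits=(2_000.0, 4_000.0))


def three_pop_model_faithful(n_snps: int = 5000) -> DemographyConfig:
    """Three-population design matched to the inference model exactly.

    For use with the forward simulator and a Beta(1,1) root: censuses and
    split times are chosen so the true autosomal drift times are
    tau = (0.1, 0.133, 0.133, 0.2) with the internal branch longest, and
    the X layer sits at the balanced ratio tau_X = tau_A / 0.75.
    """
    branches = {
        1: BranchDemography(500, 500),      # Ne_A 1000, 200 gen -> 0.1
        2: BranchDemography(375, 375),      # Ne_A 750,  200 gen -> 0.1333
        3: BranchDemography(750, 750),      # Ne_A 1500, 400 gen -> 0.1333
        4: BranchDemography(250, 250),      # Ne_A 500,  200 gen -> 0.2
        5: BranchDemography(5_000, 5_000),
    }
    return _three_pop(branches, n_snps, mutation_rate=1e-7)


def four_pop_model_faithful(n_snps: int = 5000) -> DemographyConfig:
    """Balanced four-population design with Ne_A = 1,000 / Ne_X = 750.

    Every branch has 500 females and 500 males; with both cherry splits
    at 200 generations and the root split at 400, every branch (external
    and internal) has tau_A = 0.1 and tau_X = 0.1333.  For forward-mode
    simulation of strictly independent SNPs.
    """
    branches = {i: BranchDemography(500, 500) for i in range(1, 7)}
    branches[7] = BranchDemography(5_000, 5_000)
    return _four_pop(branches, n_snps, splits=(200.0, 400.0))
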