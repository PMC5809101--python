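"""Posterior summaries: per-branch ESR, support statistic, Q ratio, DIC.

The effective sex ratio (ESR) xi is the female share of the effective
population.  Because the autosomal and X-linked effective sizes are both
set by the same female/male censuses, the per-branch drift times satisfy

    xi = 2 - (9/8) * tau_X / tau_A,

so xi = 0.5 corresponds to Q = tau_A / tau_X = 3/4, and 0 < xi < 1 pins
tau_A / tau_X into (9/16, 9/8) ("the wedge").  xi is computed per posterior
draw and summarized afterwards; the ratio of posterior-mean drift times, Q,
is reported separately.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd


def esr_from_branch_lengths(tau_a, tau_x):
    """Effective sex ratio xi = 2 - (9/8) tau_X/tau_A, in (0, 1).

    Raises a domain error when the pair lies outside the wedge
    9 tau_X/16 < tau_A < 9 tau_X/8 implied by 0 < xi < 1.
    """
    ta = np.asarray(tau_a, dtype=float)
    tx = np.asarray(tau_x, dtype=float)
    if np.any(ta <= 0) or np.any(tx <= 0):
        raise ValueError("drift times must be positive")
    xi = 2.0 - 9.0 * tx / (8.0 * ta)
    if np.any(xi <= 0.0) or np.any(xi >= 1.0):
        raise ValueError(
            "(tau_A, tau_X) outside the support 9*tau_X/16 < tau_A < 9*tau_X/8"
        )
    return float(xi) if np.ndim(tau_a) == 0 and np.ndim(tau_x) == 0 else xi


def q_ratio(tau_a, tau_x):
    """Q = tau_A / tau_X; equals 0.75 under a balanced ESR (xi = 0.5)."""
    out = np.asarray(tau_a, dtype=float) / np.asarray(tau_x, dtype=float)
    return float(out) if np.ndim(tau_a) == 0 and np.ndim(tau_x) == 0 else out


def support_statistic(xi_draws) -> float:
    """Support S = 1 - 2|p - 0.5| for the hypothesis xi != 0.5.

    p is the fraction of posterior draws with xi > 0.5 (draws exactly at
    0.5 count as "not greater").  S near 1 means no evidence of departure;
    S = 0.05 means 97.5% of draws fall on one side of 0.5.
    """
    draws = np.asarray(xi_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    p = float(np.mean(draws > 0.5))
    return 1.0 - 2.0 * abs(p - 0.5)


@dataclass
class BranchSummary:
    """Posterior summary for one branch of the population tree."""

    branch: int
    label: str
    tau_a_mean: float
    tau_a_q025: float
    tau_a_q975: float
    tau_x_mean: float
    tau_x_q025: float
    tau_x_q975: float
    xi_mean: float
    xi_median: float
    xi_q025: float
    xi_q975: float
    q: float
    support: float
    p_greater: float


def summarize(chain, tree) -> list[BranchSummary]:
    """Per-branch posterior summaries from a :class:`PosteriorChain`.

    xi is summarized from per-draw transformed values (not from the ratio
    of posterior means, which would carry a Jensen gap); Q is the ratio of
    the posterior mean drift times.
    """
    out = []
    for b, branch in enumerate(chain.branch_ids):
        ta = chain.tau["A"][:, b]
        tx = chain.tau["X"][:, b]
        xi = esr_from_branch_lengths(ta, tx)
        p = float(np.mean(xi > 0.5))
        out.append(
            BranchSummary(
                branch=branch,
                label=tree.branch_label(branch),
                tau_a_mean=float(ta.mean()),
                tau_a_q025=float(np.quantile(ta, 0.025)),
                tau_a_q975=float(np.quantile(ta, 0.975)),
                tau_x_mean=float(tx.mean()),
                tau_x_q025=float(np.quantile(tx, 0.025)),
                tau_x_q975=float(np.quantile(tx, 0.975)),
                xi_mean=float(xi.mean()),
                xi_median=float(np.median(xi)),
                xi_q025=float(np.quantile(xi, 0.025)),
                xi_q975=float(np.quantile(xi, 0.975)),
                q=float(ta.mean() / tx.mean()),
                support=1.0 - 2.0 * abs(p - 0.5),
                p_greater=p,
            )
        )
    return out


def summaries_to_frame(summaries: list[BranchSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


@dataclass
class DicResult:
    """Deviance information criterion for one fitted model/topology.

    DIC = 2*Dbar - D(theta_bar), with Dbar the posterior mean deviance and
    D(theta_bar) the deviance at the posterior means of the latent
    frequencies and branch lengths.  Lower is better; differences, not
    absolute values, are meaningful.
    """

    dbar: float
    d_at_mean: float
    dic: float
    p_d: float  # effective number of parameters, Dbar - D(theta_bar)
    label: str = ""


def compute_dic(chain, data, tree, label: str = "") -> DicResult:
    """DIC from a chain's recorded deviances and running posterior means."""
    from esrtree.mcmc import deviance_at_means

    if chain.deviance.size == 0:
        raise ValueError("chain carries no deviance records")
    dbar = float(chain.deviance.mean())
    d_mean = deviance_at_means(chain, data, tree)
    return DicResult(
        dbar=dbar,
        d_at_mean=d_mean,
        dic=2.0 * dbar - d_mean,
        p_d=dbar - d_mean,
        label=label,
    )


def dic_table(results: list[DicResult]) -> pd.DataFrame:
    """Ranked (ascending DIC) comparison table across topologies/models."""
    df = pd.DataFrame([asdict(r) for r in results])
    return df.sort_values("dic").reset_index(drop=True)


def write_dic_json(results: list[DicResult], path) -> None:
    ranked = dic_table(results)
    with open(path, "w") as fh:
        json.dump(ranked.to_dict(orient="records"), fh, indent=2)
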