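"""Mismatch distributions, sudden-expansion fitting and expansion dating.

The demographic model is the sudden (stepwise) expansion of Rogers &
Harpending (1992): a population at equilibrium diversity theta0 grows
instantaneously to theta1, tau mutational time units before present
(tau = 2*u*t for a segment-wide mutation rate u).  The expected
distribution of pairwise differences i generations after the event is

    F_i(tau, theta0, theta1) = F^_i(theta1)
        + exp(-tau (theta1+1)/theta1)
          * sum_{j=0..i} tau^j/j! (F^_{i-j}(theta0) - F^_{i-j}(theta1))

with the equilibrium distribution F^_i(theta) = theta^i/(1+theta)^{i+1}.
In the theta0 -> 0, theta1 -> inf limit this collapses to Poisson(tau), so
the mean of a post-expansion mismatch distribution estimates tau directly.

Parameters are estimated by minimising the sum of squared deviations (SSD)
between observed and expected mismatch frequencies (coarse grid over
(theta0, tau) with theta1 profiled at its upper cap, then Nelder-Mead
refinement); goodness of fit is a parametric bootstrap on SSD under the
fitted model.

Two dating calibrations are provided: (1) tau = 2*mu*t with a segment-wide
yearly rate mu estimated from parsimony mutation counts on a tree with an
age-calibrated node, and (2) a two-anchor regression through (tau, age)
pairs fixed by archaeological records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize

from .seqio import Alignment
from .popgen_stats import _pairwise_diff_counts, _site_matrix

THETA1_CAP = 99999.0  # conventional "infinite" post-expansion diversity

__all__ = [
    "MismatchFit",
    "mismatch_histogram",
    "expected_mismatch",
    "fit_sudden_expansion",
    "ssd_test",
    "fitch_mutation_count",
    "root_to_tip_counts",
    "estimate_mu",
    "time_from_tau",
    "calibrate_dates",
]


# ---------------------------------------------------------------------------
# mismatch distribution


def mismatch_histogram(a: Alignment, sites: Sequence[int]) -> np.ndarray:
    """Histogram of pairwise difference counts (index i = #pairs at i
    differences); sums to n(n-1)/2."""
    if a.n < 2:
        raise ValueError("mismatch distribution needs n >= 2")
    diffs = _pairwise_diff_counts(_site_matrix(a, list(sites)))
    return np.bincount(diffs)


def _equilibrium(theta: float, imax: int) -> np.ndarray:
    i = np.arange(imax + 1)
    if theta <= 0:
        out = np.zeros(imax + 1)
        out[0] = 1.0
        return out
    return theta**i / (1.0 + theta) ** (i + 1)


def expected_mismatch(
    imax: int, theta0: float, theta1: float, tau: float
) -> np.ndarray:
    """Expected pairwise-difference probabilities F_i for i = 0..imax under
    the sudden-expansion model."""
    F1 = _equilibrium(theta1, imax)
    F0 = _equilibrium(theta0, imax)
    if tau <= 0:
        return F0.copy()
    decay = math.exp(-tau * (theta1 + 1.0) / theta1) if theta1 > 0 else math.exp(-tau)
    # Poisson weights tau^j/j!
    logw = np.arange(imax + 1) * math.log(tau) - np.cumsum(
        np.concatenate([[0.0], np.log(np.arange(1, imax + 1))])
    )
    w = np.exp(logw)
    diff = F0 - F1
    conv = np.array([np.dot(w[: i + 1], diff[i::-1]) for i in range(imax + 1)])
    return F1 + decay * conv


@dataclass
class MismatchFit:
    histogram: np.ndarray
    n: int
    theta0: float
    theta1: float
    tau: float
    ssd: float
    converged: bool = True
    p_ssd: float | None = None

    @property
    def observed_freq(self) -> np.ndarray:
        return self.histogram / self.histogram.sum()


def _ssd(obs_freq: np.ndarray, theta0: float, theta1: float, tau: float) -> float:
    exp = expected_mismatch(len(obs_freq) - 1, theta0, theta1, tau)
    return float(np.sum((obs_freq - exp) ** 2))


def fit_sudden_expansion(histogram: np.ndarray, n: int | None = None) -> MismatchFit:
    """Least-SSD fit of (theta0, theta1, tau) to an observed mismatch
    histogram.

    A coarse grid over (theta0, tau) with theta1 profiled at its cap seeds
    a Nelder-Mead refinement of all three parameters (theta1 bounded by
    the cap, theta0 <= theta1, tau >= 0).  Deterministic for a given
    histogram.
    """
    hist = np.asarray(histogram, dtype=float)
    total = hist.sum()
    if total <= 0 or len(hist) < 2:
        raise ValueError("degenerate mismatch histogram")
    if n is None:
        n = int(round((1 + math.sqrt(1 + 8 * total)) / 2))
    obs = hist / total
    mean_diff = float(np.dot(np.arange(len(hist)), obs))

    tau_grid = np.unique(
        np.concatenate(
            [np.linspace(0.0, max(2.0 * mean_diff, 2.0), 25), [mean_diff]]
        )
    )
    theta0_grid = np.array([0.0, 0.1, 0.5, 1.0, 2.0, max(mean_diff, 0.5)])
    best = (np.inf, 0.0, THETA1_CAP, mean_diff)
    for t0 in theta0_grid:
        for tau in tau_grid:
            s = _ssd(obs, t0, THETA1_CAP, tau)
            if s < best[0]:
                best = (s, t0, THETA1_CAP, tau)

    def objective(x: np.ndarray) -> float:
        t0, t1, tau = x
        if not (0.0 <= t0 <= t1 <= THETA1_CAP and tau >= 0.0):
            return 1e6
        return _ssd(obs, t0, t1, tau)

    res = optimize.minimize(
        objective,
        x0=np.array([best[1], best[2], best[3]]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    if res.fun <= best[0]:
        t0, t1, tau = res.x
        ssd_val, converged = float(res.fun), bool(res.success)
    else:  # keep the grid optimum if refinement wandered off
        ssd_val, t0, t1, tau = best
        converged = False
    return MismatchFit(hist.astype(int), n, float(t0), float(t1), float(tau),
                       ssd_val, converged)


def ssd_test(
    fit: MismatchFit,
    n: int,
    locus_length: int,
    replicates: int = 1000,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap p-value for the sudden-expansion fit.

    Coalescent samples are simulated under the fitted expansion, each is
    refitted with the same optimiser, and p is the fraction of simulated
    SSD values at least as large as the observed one.  Small p rejects the
    expansion model.
    """
    from .synthetic_data import simulate_coalescent

    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    demog = {"theta0": fit.theta0, "theta1": fit.theta1, "tau": fit.tau}
    count = 0
    for _ in range(replicates):
        sub = int(rng.integers(1, 2**31 - 1))
        _, aln = simulate_coalescent(n, demog, locus_length, sub)
        hist = mismatch_histogram(aln, range(aln.length))
        sim_fit = fit_sudden_expansion(hist, n)
        # SSD of the simulated data against its own best fit
        if sim_fit.ssd >= fit.ssd - 1e-15:
            count += 1
    p = count / replicates
    fit.p_ssd = p
    return p


# ---------------------------------------------------------------------------
# parsimony mutation counting


def _allowed_states(ch: str) -> tuple[str, ...]:
    return ("A", "C", "G", "T") if ch in ("N", "-") else (ch,)


def fitch_mutation_count(
    tree: dendropy.Tree,
    a: Alignment,
    mode: str = "fractional",
) -> tuple[int, dict[dendropy.Node, float]]:
    """Small-parsimony mutation counts per branch.

    Runs unit-cost Sankoff dynamic programming per alignment column and
    attributes mutations to branches (each branch keyed by its child
    node).  With ``mode="fractional"`` a column with several equally
    parsimonious reconstructions spreads its mutations as the expected
    count under a uniform distribution over all optimal assignments; with
    ``mode="first"`` one optimal assignment is chosen deterministically
    (lexicographically smallest state at each step).  The total over
    branches equals the parsimony score in both modes.
    """
    if mode not in ("fractional", "first"):
        raise ValueError("mode must be 'fractional' or 'first'")
    seq_of = dict(zip(a.ids, a.seqs))
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [lf for lf in leaves if lf not in seq_of]
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {missing[:5]}")
    states = ("A", "C", "G", "T")
    sidx = {s: i for i, s in enumerate(states)}
    nodes = list(tree.postorder_node_iter())
    parent_first = list(tree.preorder_node_iter())
    branch: dict[dendropy.Node, float] = {nd: 0.0 for nd in nodes}
    total_score = 0
    INF = 1e18

    for col in range(a.length):
        cost: dict[dendropy.Node, np.ndarray] = {}
        count: dict[dendropy.Node, np.ndarray] = {}
        for nd in nodes:
            if nd.is_leaf():
                ch = seq_of[nd.taxon.label][col]
                c = np.full(4, INF)
                k = np.zeros(4)
                for s in _allowed_states(ch):
                    c[sidx[s]] = 0.0
                    k[sidx[s]] = 1.0
                cost[nd], count[nd] = c, k
            else:
                c = np.zeros(4)
                k = np.ones(4)
                for child in nd.child_nodes():
                    cc = cost[child]
                    # transition cost from parent state s to child state t
                    trans = cc[None, :] + (1.0 - np.eye(4))
                    m = trans.min(axis=1)
                    kk = np.array(
                        [
                            count[child][np.isclose(trans[s], m[s])].sum()
                            for s in range(4)
                        ]
                    )
                    c = c + m
                    k = k * kk
                cost[nd], count[nd] = c, k
        root = tree.seed_node
        score = cost[root].min()
        if score <= 0:
            continue  # invariant column
        total_score += int(round(score))

        if mode == "first":
            # top-down: pick lexicographically smallest optimal state
            choice: dict[dendropy.Node, int] = {}
            r_opt = np.flatnonzero(np.isclose(cost[root], score))
            choice[root] = int(r_opt[0])
            for nd in parent_first:
                if nd is root:
                    continue
                s = choice[nd.parent_node]
                cc = cost[nd]
                trans = cc + (np.arange(4) != s)
                t = int(np.flatnonzero(np.isclose(trans, trans.min()))[0])
                choice[nd] = t
                if t != s:
                    branch[nd] += 1.0
        else:
            # up-down counting of optimal assignments
            opt: dict[dendropy.Node, np.ndarray] = {}  # outside-counts O_v(s)
            r_opt = np.isclose(cost[root], score)
            o = np.zeros(4)
            o[r_opt] = 1.0
            opt[root] = o
            total_opt = float((count[root] * o).sum())
            for nd in parent_first:
                if nd.is_leaf():
                    continue
                children = nd.child_nodes()
                # per-child B_b(s) = sum of counts over optimal child states
                B = {}
                argmin_mask = {}
                for child in children:
                    cc = cost[child]
                    trans = cc[None, :] + (1.0 - np.eye(4))
                    m = trans.min(axis=1)
                    mask = np.isclose(trans, m[:, None])
                    argmin_mask[child] = mask
                    B[child] = mask @ count[child]
                for child in children:
                    o_child = np.zeros(4)
                    e_mut = 0.0
                    for s in range(4):
                        if opt[nd][s] == 0:
                            continue
                        sib = opt[nd][s]
                        for other in children:
                            if other is not child:
                                sib *= B[other][s]
                        mask = argmin_mask[child][s]
                        o_child[mask] += sib
                        mut_states = mask & (np.arange(4) != s)
                        e_mut += sib * float(count[child][mut_states].sum())
                    opt[child] = o_child
                    if total_opt > 0:
                        branch[child] += e_mut / total_opt
    return total_score, branch


def root_to_tip_counts(
    tree: dendropy.Tree,
    branch_counts: Mapping[dendropy.Node, float],
    node: dendropy.Node | None = None,
) -> dict[str, float]:
    """Summed branch mutation counts from ``node`` (default: root) down to
    each descendant leaf."""
    if node is None:
        node = tree.seed_node
    out: dict[str, float] = {}

    def walk(nd: dendropy.Node, acc: float) -> None:
        if nd.is_leaf():
            out[nd.taxon.label] = acc
            return
        for child in nd.child_nodes():
            walk(child, acc + branch_counts.get(child, 0.0))

    for child in node.child_nodes():
        walk(child, branch_counts.get(child, 0.0))
    if node.is_leaf():
        out[node.taxon.label] = 0.0
    return out


def estimate_mu(
    tree: dendropy.Tree,
    branch_counts: Mapping[dendropy.Node, float],
    node: dendropy.Node,
    age_years: float,
) -> float:
    """Segment-wide yearly mutation rate from a calibrated node.

    mu = mean over tips below the node of (path mutation count / age).
    """
    if age_years <= 0:
        raise ValueError("calibration age must be positive")
    tips = root_to_tip_counts(tree, branch_counts, node)
    if not tips:
        raise ValueError("calibration node has no descendant tips")
    return float(np.mean([c / age_years for c in tips.values()]))


def mrca(tree: dendropy.Tree, leaf_labels: Sequence[str]) -> dendropy.Node:
    """Most recent common ancestor of the named leaves."""
    taxa = [t for t in tree.taxon_namespace if t.label in set(leaf_labels)]
    if len(taxa) < len(set(leaf_labels)):
        raise ValueError("some labels not found in tree")
    return tree.mrca(taxa=taxa)


# ---------------------------------------------------------------------------
# dating


def time_from_tau(tau: float, mu: float, generation_time: float = 1.0) -> float:
    """Expansion age from tau = 2*mu*t: t = tau / (2 mu), in years when mu
    is the segment-wide per-year rate (generation_time rescales when mu is
    per generation)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return tau / (2.0 * mu) * generation_time


def calibrate_dates(
    anchors: Sequence[tuple[float, float]],
    taus: Sequence[float],
    intervals: Sequence[tuple[float, float]] | None = None,
) -> list[dict[str, float]]:
    """Regression dating through (tau, years B.P.) anchor points.

    With two anchors the line is exact; with more, ordinary least squares.
    Query tau values are mapped through the line; optional (lo, hi) tau
    intervals are propagated through the same line (endpoints reordered if
    the slope is negative).
    """
    anchors = list(anchors)
    if len(anchors) < 2:
        raise ValueError("need at least two anchors")
    xs = np.array([t for t, _ in anchors], dtype=float)
    ys = np.array([y for _, y in anchors], dtype=float)
    if len(np.unique(xs)) < 2:
        raise ValueError("anchor tau values must be distinct")
    slope, intercept = np.polyfit(xs, ys, 1)
    out = []
    for i, tau in enumerate(taus):
        row = {"tau": float(tau), "date_bp": float(slope * tau + intercept)}
        if intervals is not None:
            lo, hi = intervals[i]
            d1, d2 = slope * lo + intercept, slope * hi + intercept
            row["date_lo"], row["date_hi"] = float(min(d1, d2)), float(max(d1, d2))
        out.append(row)
    return out
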