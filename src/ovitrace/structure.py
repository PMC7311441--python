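"""Population structure: haplogroup assignment, AMOVA and composition tables.

AMOVA follows the hierarchical variance decomposition of Excoffier,
Smouse & Quattro (1992) on pairwise nucleotide-difference distances:
variance is partitioned among groups, among populations (breeds) within
groups, and within populations, with Phi statistics and permutation
p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import Alignment

__all__ = [
    "AmovaResult",
    "assign_haplogroups",
    "pairwise_difference_matrix",
    "amova",
    "composition_report",
    "round_half_up",
]


def assign_haplogroups(
    a: Alignment,
    refs: Mapping[str, str],
    sites: Sequence[int] | None = None,
) -> tuple[dict[str, str | None], set[str]]:
    """Label each sequence with the haplogroup of its nearest reference.

    ``refs`` maps haplogroup name (e.g. A..E) to a reference sequence
    aligned to the same coordinate system.  Distance is Hamming over the
    site set.  Ties are flagged: tied ids get label ``None`` and are
    returned in the ambiguous set.  Assignment is invariant to reference
    ordering.
    """
    if sites is None:
        sites = range(a.length)
    sites = list(sites)
    names = sorted(refs)
    R = np.frombuffer(
        "".join("".join(refs[r][j] for j in sites) for r in names).encode("ascii"),
        dtype="S1",
    ).reshape(len(names), len(sites))
    M = a.matrix()[:, sites]
    labels: dict[str, str | None] = {}
    ambiguous: set[str] = set()
    for i, sid in enumerate(a.ids):
        d = (R != M[i]).sum(axis=1)
        best = d.min()
        winners = [names[j] for j in np.flatnonzero(d == best)]
        if len(winners) > 1:
            labels[sid] = None
            ambiguous.add(sid)
        else:
            labels[sid] = winners[0]
    return labels, ambiguous


def pairwise_difference_matrix(a: Alignment, sites: Sequence[int] | None = None) -> np.ndarray:
    """Full n x n matrix of pairwise nucleotide difference counts."""
    if sites is None:
        sites = range(a.length)
    M = a.matrix()[:, list(sites)]
    n = M.shape[0]
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        D[i] = (M != M[i]).sum(axis=1)
    return D


@dataclass
class AmovaResult:
    """Nested AMOVA decomposition with Phi statistics and permutation p-values."""

    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    pct_among_groups: float
    pct_among_pops: float
    pct_within: float
    phi_CT: float
    phi_SC: float
    phi_ST: float
    p_CT: float | None = None
    p_SC: float | None = None
    p_ST: float | None = None
    df: dict[str, int] = field(default_factory=dict)

    @property
    def total_variance(self) -> float:
        return self.sigma_among_groups + self.sigma_among_pops + self.sigma_within


def _amova_components(
    D2: np.ndarray, pops: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float, dict[str, int]]:
    """Variance components from squared distances via nested sums of squares."""
    N = D2.shape[0]
    pop_ids = np.unique(pops)
    grp_ids = np.unique(groups)
    P, G = len(pop_ids), len(grp_ids)

    def ss(idx: np.ndarray) -> float:
        # sum over unordered pairs of squared distance / subset size
        sub = D2[np.ix_(idx, idx)]
        return float(sub.sum() / 2.0 / len(idx))

    all_idx = np.arange(N)
    ss_total = ss(all_idx)
    ss_wp = sum(ss(np.flatnonzero(pops == p)) for p in pop_ids)
    ss_wg = sum(ss(np.flatnonzero(groups == g)) for g in grp_ids)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    df = {"among_groups": G - 1, "among_pops": P - G, "within": N - P}
    msd_wp = ss_wp / df["within"] if df["within"] > 0 else 0.0
    sigma_c = msd_wp

    pop_sizes = {p: int((pops == p).sum()) for p in pop_ids}
    grp_sizes = {g: int((groups == g).sum()) for g in grp_ids}
    pop_group = {p: groups[pops == p][0] for p in pop_ids}
    sum_np2_over_ng = sum(
        sum(pop_sizes[p] ** 2 for p in pop_ids if pop_group[p] == g) / grp_sizes[g]
        for g in grp_ids
    )
    if P > G:
        n_coef = (N - sum_np2_over_ng) / (P - G)
        msd_ap = ss_ap / df["among_pops"]
        sigma_b = (msd_ap - sigma_c) / n_coef
    else:
        sigma_b = 0.0
    if G > 1:
        n_prime = (sum_np2_over_ng - sum(pop_sizes[p] ** 2 for p in pop_ids) / N) / (G - 1)
        n_dprime = (N - sum(grp_sizes[g] ** 2 for g in grp_ids) / N) / (G - 1)
        msd_ag = ss_ag / df["among_groups"]
        sigma_a = (msd_ag - sigma_c - n_prime * sigma_b) / n_dprime
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c, df


def amova(
    distances: np.ndarray,
    pop_labels: Sequence[str],
    group_labels: Sequence[str],
    permutations: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA on a pairwise distance matrix.

    Parameters
    ----------
    distances:
        n x n matrix of pairwise nucleotide difference counts (treated as
        squared Euclidean distances, the mtDNA convention).
    pop_labels, group_labels:
        Per-sequence breed and group labels (group constant within breed).
    permutations:
        Permutation count for p-values (0 to skip).  Phi_ST permutes
        individuals among breeds overall, Phi_SC within groups, Phi_CT
        permutes whole breeds among groups.

    Populations of size 1 are excluded with a warning (they carry no
    within-population information).
    """
    D = np.asarray(distances, dtype=float)
    pops = np.asarray(pop_labels)
    groups = np.asarray(group_labels)
    if D.shape[0] != len(pops) or len(pops) != len(groups):
        raise ValueError("distance matrix and labels are inconsistent")
    for p in np.unique(pops):
        gs = np.unique(groups[pops == p])
        if len(gs) > 1:
            raise ValueError(f"population {p!r} spans multiple groups")
    sizes = pd.Series(pops).value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding populations with n=1: {small}")
        keep = np.flatnonzero(~np.isin(pops, small))
        D = D[np.ix_(keep, keep)]
        pops, groups = pops[keep], groups[keep]
    if len(np.unique(pops)) < 2:
        raise ValueError("AMOVA needs at least two populations")

    D2 = D  # difference counts are already squared Euclidean distances
    sigma_a, sigma_b, sigma_c, df = _amova_components(D2, pops, groups)
    total = sigma_a + sigma_b + sigma_c
    if total <= 0:
        pct = (0.0, 0.0, 100.0) if sigma_c == 0 else (0.0, 0.0, 100.0)
        phi_ct = phi_sc = phi_st = 0.0
    else:
        pct = (100 * sigma_a / total, 100 * sigma_b / total, 100 * sigma_c / total)
        phi_ct = sigma_a / total
        phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0
        phi_st = (sigma_a + sigma_b) / total
    result = AmovaResult(
        sigma_a, sigma_b, sigma_c, pct[0], pct[1], pct[2],
        phi_ct, phi_sc, phi_st, df=df,
    )
    if permutations > 0:
        rng = np.random.default_rng(seed)
        n = len(pops)
        ge_st = ge_sc = ge_ct = 0
        pop_ids = np.unique(pops)
        pop_group = {p: groups[pops == p][0] for p in pop_ids}
        for _ in range(permutations):
            # Phi_ST: permute individuals among populations (and groups)
            perm = rng.permutation(n)
            sa, sb, sc, _ = _amova_components(D2, pops[perm], groups[perm])
            tot = sa + sb + sc
            if tot > 0 and (sa + sb) / tot >= phi_st - 1e-12:
                ge_st += 1
            # Phi_SC: permute individuals among populations within groups
            perm2 = np.arange(n)
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                perm2[idx] = idx[rng.permutation(len(idx))]
            sa, sb, sc, _ = _amova_components(D2, pops[perm2], groups)
            if (sb + sc) > 0 and sb / (sb + sc) >= phi_sc - 1e-12:
                ge_sc += 1
            # Phi_CT: permute whole populations among groups
            shuffled = rng.permutation([pop_group[p] for p in pop_ids])
            gmap = dict(zip(pop_ids, shuffled))
            gperm = np.asarray([gmap[p] for p in pops])
            sa, sb, sc, _ = _amova_components(D2, pops, gperm)
            tot = sa + sb + sc
            if tot > 0 and sa / tot >= phi_ct - 1e-12:
                ge_ct += 1
        result.p_ST = (ge_st + 1) / (permutations + 1)
        result.p_SC = (ge_sc + 1) / (permutations + 1)
        result.p_CT = (ge_ct + 1) / (permutations + 1)
    return result


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (119/193 -> 62%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def composition_report(
    labels: Sequence[str], categories: Sequence[str] | None = None
) -> pd.DataFrame:
    """Counts and integer-rounded percentages per category.

    Percentages are rounded half away from zero, reproducing conventional
    reporting of haplogroup / network-group compositions (e.g. 185 of 193
    -> 96%).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no labels supplied")
    total = len(labels)
    counts = pd.Series(labels).value_counts()
    if categories is not None:
        counts = counts.reindex(list(categories), fill_value=0)
    else:
        counts = counts.sort_index()
    pct = counts.apply(lambda c: round_half_up(100.0 * c / total))
    return pd.DataFrame({"count": counts.astype(int), "percent": pct.astype(int)})
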