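"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: statistics
are recomputed with explicit loops and, for Fu's Fs, with the Stirling
number form of the Ewens distribution instead of the sequential
(Poisson-binomial) recursion.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, product


def pair_diffs(seqs: list[str]) -> list[int]:
    return [sum(c1 != c2 for c1, c2 in zip(a, b)) for a, b in combinations(seqs, 2)]


def mean_k(seqs: list[str]) -> float:
    d = pair_diffs(seqs)
    return sum(d) / len(d)


def column_alleles(seqs: list[str]) -> list[dict[str, int]]:
    out = []
    for j in range(len(seqs[0])):
        col = [s[j] for s in seqs]
        counts = {}
        for ch in "ACGT":
            c = col.count(ch)
            if c:
                counts[ch] = c
        out.append(counts)
    return out


def site_classes(seqs: list[str]) -> tuple[int, int, int]:
    S = Sg = P = 0
    for counts in column_alleles(seqs):
        vals = sorted(counts.values())
        if len(vals) < 2:
            continue
        S += 1
        if len(vals) == 2 and vals[0] == 1:
            Sg += 1
        if len([v for v in vals if v >= 2]) >= 2:
            P += 1
    return S, Sg, P


def eta_counts(seqs: list[str]) -> tuple[int, int]:
    eta = eta_s = 0
    for counts in column_alleles(seqs):
        if len(counts) >= 2:
            eta += len(counts) - 1
            eta_s += sum(1 for v in counts.values() if v == 1)
    return eta, eta_s


def tajima_D(seqs: list[str]) -> float:
    n = len(seqs)
    S = site_classes(seqs)[0]
    if S == 0:
        return float("nan")
    k = mean_k(seqs)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = float(e1) * S + float(e2) * S * (S - 1)
    return (k - S / float(a1)) / math.sqrt(var)


def fu_li_Dstar_Fstar(seqs: list[str]) -> tuple[float, float]:
    n = len(seqs)
    eta, eta_s = eta_counts(seqs)
    if eta == 0:
        return float("nan"), float("nan")
    k = mean_k(seqs)
    an = sum(Fraction(1, i) for i in range(1, n))
    bn = sum(Fraction(1, i * i) for i in range(1, n))
    an1 = an + Fraction(1, n)
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + Fraction(n - 2, (n - 1) ** 2)
        + Fraction(2, n - 1) * (Fraction(3, 2) - (2 * an1 - 3) / (n - 2) - Fraction(1, n))
    )
    nn = Fraction(n)
    vD = (
        (nn / (n - 1)) ** 2 * bn
        + an**2 * dn
        - 2 * (n * an * (an + 1)) / Fraction((n - 1) ** 2)
    ) / (an**2 + bn)
    uD = (nn / (n - 1)) * (an - nn / (n - 1)) - vD
    vF = (
        dn
        + Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
        - Fraction(2, n - 1) * (4 * bn - 6 + Fraction(8, n))
    ) / (an**2 + bn)
    uF = (
        nn / (n - 1)
        + Fraction(n + 1, 3 * (n - 1))
        - Fraction(4, n * (n - 1))
        + Fraction(2 * (n + 1), (n - 1) ** 2) * (an1 - Fraction(2 * n, n + 1))
    ) / an - vF
    Dstar = (float(nn / (n - 1)) * eta - float(an) * eta_s) / math.sqrt(
        float(uD) * eta + float(vD) * eta * eta
    )
    Fstar = (k - float(Fraction(n - 1, n)) * eta_s) / math.sqrt(
        float(uF) * eta + float(vF) * eta * eta
    )
    return Dstar, Fstar


def unsigned_stirling_first(n: int) -> list[list[int]]:
    """Table c[m][j] of unsigned Stirling numbers of the first kind."""
    c = [[0] * (n + 1) for _ in range(n + 1)]
    c[0][0] = 1
    for m in range(1, n + 1):
        for j in range(1, m + 1):
            c[m][j] = c[m - 1][j - 1] + (m - 1) * c[m - 1][j]
    return c


def ewens_pmf_stirling(n: int, theta: float) -> list[float]:
    """P(K = j) via |S(n, j)| theta^j / theta^{(n)}."""
    c = unsigned_stirling_first(n)
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    return [c[n][j] * theta**j / rising for j in range(n + 1)]


def fu_Fs(seqs: list[str]) -> float:
    k = mean_k(seqs)
    if k == 0:
        return float("nan")
    k_obs = len(set(seqs))
    if k_obs <= 1:
        return float("inf")
    pmf = ewens_pmf_stirling(len(seqs), k)
    s = sum(pmf[k_obs:])
    return math.log(s / (1.0 - s))


def dxy_da(X: list[str], Y: list[str]) -> tuple[float, float]:
    L = len(X[0])
    cross = [
        sum(c1 != c2 for c1, c2 in zip(x, y)) for x in X for y in Y
    ]
    dxy = sum(cross) / len(cross) / L

    def within(Z):
        n = len(Z)
        if n < 2:
            return 0.0
        # frequency-weighted: all ordered pairs incl. self-pairs
        return 2.0 * sum(pair_diffs(Z)) / (n * n) / L

    return dxy, dxy - (within(X) + within(Y)) / 2.0


def fitch_score_exhaustive(adjacency: dict, leaves: dict[str, str]) -> int:
    """Exhaustive small-parsimony score for one column.

    ``adjacency`` maps internal node name -> list of child names; leaf
    names map to their state in ``leaves``.  Tries every assignment of
    states to internal nodes.
    """
    internal = sorted(adjacency)
    best = math.inf
    for combo in product("ACGT", repeat=len(internal)):
        state = dict(zip(internal, combo))
        state.update(leaves)
        cost = sum(
            state[p] != state[c] for p in adjacency for c in adjacency[p]
        )
        best = min(best, cost)
    return int(best)


def amova_components_oracle(
    d2, pops: list[str], groups: list[str]
) -> tuple[float, float, float]:
    """Nested AMOVA variance components from explicit sums of squares."""
    import numpy as np

    d2 = np.asarray(d2, dtype=float)
    N = len(pops)
    pop_ids = sorted(set(pops))
    grp_ids = sorted(set(groups))
    P, G = len(pop_ids), len(grp_ids)

    def ss(idx):
        tot = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                tot += d2[idx[a], idx[b]]
        return tot / len(idx)

    everyone = list(range(N))
    ss_tot = ss(everyone)
    ss_wp = sum(ss([i for i in everyone if pops[i] == p]) for p in pop_ids)
    ss_wg = sum(ss([i for i in everyone if groups[i] == g]) for g in grp_ids)
    df_wp = N - P
    sigma_c = ss_wp / df_wp
    n_p = {p: pops.count(p) for p in pop_ids}
    n_g = {g: groups.count(g) for g in grp_ids}
    grp_of = {p: groups[pops.index(p)] for p in pop_ids}
    s1 = sum(
        sum(n_p[p] ** 2 for p in pop_ids if grp_of[p] == g) / n_g[g] for g in grp_ids
    )
    ncoef = (N - s1) / (P - G)
    sigma_b = ((ss_wg - ss_wp) / (P - G) - sigma_c) / ncoef
    nprime = (s1 - sum(n_p[p] ** 2 for p in pop_ids) / N) / (G - 1)
    ndprime = (N - sum(n_g[g] ** 2 for g in grp_ids) / N) / (G - 1)
    sigma_a = ((ss_tot - ss_wg) / (G - 1) - sigma_c - nprime * sigma_b) / ndprime
    return sigma_a, sigma_b, sigma_c
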