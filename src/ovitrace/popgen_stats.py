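"""Diversity indices and neutrality tests for aligned mtDNA sequences.

All statistics are computed from first principles on the retained site set:

* site classes S (segregating), Sg (singleton) and P (parsimony-informative);
* Nei's unbiased haplotype diversity Hd and nucleotide diversity pi;
* Tajima's D, Fu & Li's D* and F* (the outgroup-free, starred variants),
  and Fu's Fs from the Ewens sampling distribution of haplotype counts;
* Shannon diversity of haplogroup frequencies;
* between-population distances Dxy (raw) and Da (net of within-population
  diversity).

Statistics that are undefined on monomorphic data return ``nan`` and are
flagged as undefined in :func:`neutrality_summary` rather than reported as
zero.  Significance is assessed against a seeded coalescent-simulated null
distribution; the conventional p < 0.02 threshold is used for Fu's Fs and
two-sided 5% for the other three tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .seqio import Alignment, HaplotypeTable, collapse_haplotypes

__all__ = [
    "DiversitySummary",
    "NeutralitySummary",
    "site_classes",
    "allele_counts",
    "haplotype_diversity",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "tajima_D",
    "fu_li_tests",
    "fu_Fs",
    "shannon_index",
    "dxy_da",
    "diversity_summary",
    "neutrality_summary",
    "simulated_null_quantiles",
]


# ---------------------------------------------------------------------------
# site bookkeeping


def _site_matrix(a: Alignment, sites: Sequence[int]) -> np.ndarray:
    return a.matrix()[:, list(sites)]


def allele_counts(a: Alignment, sites: Sequence[int]) -> list[dict[bytes, int]]:
    """Per-column counts of non-missing alleles (A/C/G/T) on the site set."""
    M = _site_matrix(a, sites)
    out = []
    for j in range(M.shape[1]):
        col = M[:, j]
        counts: dict[bytes, int] = {}
        for b in (b"A", b"C", b"G", b"T"):
            c = int((col == b).sum())
            if c:
                counts[b] = c
        out.append(counts)
    return out


def site_classes(a: Alignment, sites: Sequence[int]) -> tuple[int, int, int]:
    """Count segregating (S), singleton (Sg) and parsimony-informative (P) columns.

    Sg counts strictly biallelic columns whose minor allele is carried by a
    single sequence; P counts columns with at least two alleles each present
    in two or more sequences.  A column with three alleles at counts
    (1, 1, n-2) is therefore segregating but neither Sg nor P, which is why
    ``Sg + P <= S``.
    """
    if a.n < 2:
        raise ValueError("site classes need at least two sequences")
    S = Sg = P = 0
    for counts in allele_counts(a, sites):
        vals = sorted(counts.values())
        if len(vals) < 2:
            continue
        S += 1
        if len(vals) == 2 and vals[0] == 1:
            Sg += 1
        if sum(1 for v in vals if v >= 2) >= 2:
            P += 1
    return S, Sg, P


def _eta_counts(a: Alignment, sites: Sequence[int]) -> tuple[int, int]:
    """Total mutations eta = sum over columns of (alleles - 1) and singleton
    mutations eta_s = number of alleles carried by exactly one sequence."""
    eta = eta_s = 0
    for counts in allele_counts(a, sites):
        k = len(counts)
        if k >= 2:
            eta += k - 1
            eta_s += sum(1 for v in counts.values() if v == 1)
    return eta, eta_s


# ---------------------------------------------------------------------------
# diversity


def haplotype_diversity(ht: HaplotypeTable) -> float:
    """Nei's unbiased haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    n = ht.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = np.asarray(ht.counts, dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def _pairwise_diff_counts(M: np.ndarray) -> np.ndarray:
    """Hamming differences for all sequence pairs (missing chars count as
    differences only against real bases, never against each other)."""
    n = M.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=np.int64)
    k = 0
    for i in range(n - 1):
        diffs = (M[i + 1 :] != M[i]).sum(axis=1)
        out[k : k + n - 1 - i] = diffs
        k += n - 1 - i
    return out


def mean_pairwise_differences(a: Alignment, sites: Sequence[int]) -> float:
    """k: the mean number of nucleotide differences between sequence pairs."""
    if a.n < 2:
        raise ValueError("needs at least two sequences")
    M = _site_matrix(a, sites)
    return float(_pairwise_diff_counts(M).mean())


def nucleotide_diversity(a: Alignment, sites: Sequence[int]) -> tuple[float, float]:
    """Return (pi, k): per-site nucleotide diversity and mean pairwise differences."""
    k = mean_pairwise_differences(a, sites)
    return k / len(list(sites)), k


# ---------------------------------------------------------------------------
# neutrality tests


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def tajima_D(a: Alignment, sites: Sequence[int]) -> float:
    """Tajima's D: contrast of mean pairwise differences k with Watterson's
    S/a1.  An excess of rare variants (e.g. after an expansion) drives D
    negative.  Returns ``nan`` when there is no polymorphism.
    """
    n = a.n
    S, _, _ = site_classes(a, sites)
    if S == 0:
        return float("nan")
    k = mean_pairwise_differences(a, sites)
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (k - S / a1) / math.sqrt(var)


def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """Variance constants (uD*, vD*, uF*, vF*) for the starred Fu & Li tests
    (Fu & Li 1993 with the Simonsen et al. 1995 corrections, as used by the
    standard desktop implementations)."""
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2)) if n > 2 else 1.0
    dn = (
        cn
        + (n - 2) / ((n - 1) ** 2)
        + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    vD = (
        (n / (n - 1.0)) ** 2 * bn
        + an**2 * dn
        - 2.0 * (n * an * (an + 1)) / ((n - 1.0) ** 2)
    ) / (an**2 + bn)
    uD = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vD
    vF = (
        dn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1.0))
        - (2.0 / (n - 1.0)) * (4 * bn - 6 + 8.0 / n)
    ) / (an**2 + bn)
    uF = (
        (n / (n - 1.0))
        + (n + 1) / (3.0 * (n - 1.0))
        - 4.0 / (n * (n - 1.0))
        + 2.0 * (n + 1) / ((n - 1.0) ** 2) * (an1 - 2.0 * n / (n + 1))
    ) / an - vF
    return uD, vD, uF, vF


def fu_li_tests(a: Alignment, sites: Sequence[int]) -> tuple[float, float]:
    """Fu & Li's D* and F* (no outgroup), based on total mutations eta and
    singleton mutations eta_s.  Excess singletons drive both negative."""
    n = a.n
    if n < 3:
        raise ValueError("Fu & Li tests need n >= 3")
    eta, eta_s = _eta_counts(a, sites)
    if eta == 0:
        return float("nan"), float("nan")
    an = _harmonic(n)
    k = mean_pairwise_differences(a, sites)
    uD, vD, uF, vF = _fu_li_constants(n)
    Dstar = (n / (n - 1.0) * eta - an * eta_s) / math.sqrt(uD * eta + vD * eta * eta)
    Fstar = (k - (n - 1.0) / n * eta_s) / math.sqrt(uF * eta + vF * eta * eta)
    return Dstar, Fstar


def _ewens_haplotype_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = j), j = 0..n, for the number of distinct haplotypes K in an
    Ewens sample of size n at scaled diversity theta.

    Uses the sequential (Chinese-restaurant) construction: K is a sum of
    independent Bernoulli(theta / (theta + i)) draws, i = 0..n-1, giving a
    numerically stable Poisson-binomial recursion equivalent to the Stirling
    number form |S(n, j)| theta^j / theta^{(n)}.
    """
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i in range(n):
        p = theta / (theta + i)
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - p) + p * pmf[0 : i + 1]
        pmf[0] *= 1 - p
    return pmf


def fu_Fs(a: Alignment, sites: Sequence[int]) -> float:
    """Fu's Fs: Fs = ln(S'/(1-S')) where S' = P(K >= k_obs | theta = k)
    under the Ewens sampling distribution.  Many rare haplotypes (few
    pairwise differences but many haplotypes) give strongly negative Fs.

    Returns ``nan`` when k = 0 and ``+inf`` at the k_obs = 1 boundary
    (S' = 1).
    """
    k = mean_pairwise_differences(a, sites)
    if k == 0:
        return float("nan")
    ht = collapse_haplotypes(a, sites)
    k_obs = ht.H
    n = a.n
    if k_obs <= 1:
        return float("inf")
    pmf = _ewens_haplotype_pmf(n, k)
    s_prime = float(pmf[k_obs:].sum())
    if s_prime <= 0.0:
        return float("inf")
    if s_prime >= 1.0:
        return float("-inf")
    return math.log(s_prime / (1.0 - s_prime))


def shannon_index(counts: Sequence[float]) -> float:
    """Shannon diversity H' = -sum p ln p over category counts."""
    arr = np.asarray(list(counts), dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("at least one count must be positive")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# between-population distances


def dxy_da(
    popX: Alignment, popY: Alignment, sites: Sequence[int]
) -> tuple[float, float]:
    """Raw (Dxy) and net (Da) between-population per-site divergence.

    Dxy averages per-site differences over all cross-population pairs;
    Da subtracts the mean within-population diversity, so ``Da <= Dxy``
    with equality when both populations are monomorphic.  Within-population
    diversity here follows the frequency-weighted (Nei) convention --
    averaging over all ordered sequence pairs including self-pairs -- so
    that Da is exactly 0 when the two samples are identical.
    """
    sites = list(sites)
    L = len(sites)
    MX = _site_matrix(popX, sites)
    MY = _site_matrix(popY, sites)
    total = 0
    for i in range(MX.shape[0]):
        total += int((MY != MX[i]).sum())
    dxy = total / (MX.shape[0] * MY.shape[0]) / L

    def within(M: np.ndarray) -> float:
        n = M.shape[0]
        if n < 2:
            return 0.0
        return float(_pairwise_diff_counts(M).sum()) * 2.0 / (n * n) / L

    return dxy, dxy - (within(MX) + within(MY)) / 2.0


# ---------------------------------------------------------------------------
# summaries


@dataclass
class DiversitySummary:
    n: int
    S: int
    Sg: int
    P: int
    H: int
    Hd: float
    pi: float
    k: float


@dataclass
class NeutralitySummary:
    tajima_D: float
    fu_li_Dstar: float
    fu_li_Fstar: float
    fu_Fs: float
    defined: bool
    significant: dict[str, bool] | None = None


def diversity_summary(a: Alignment, sites: Sequence[int]) -> DiversitySummary:
    S, Sg, P = site_classes(a, sites)
    ht = collapse_haplotypes(a, sites)
    pi, k = nucleotide_diversity(a, sites)
    return DiversitySummary(
        n=a.n, S=S, Sg=Sg, P=P, H=ht.H, Hd=haplotype_diversity(ht), pi=pi, k=k
    )


def simulated_null_quantiles(
    statistic: Callable[[Alignment, Sequence[int]], float],
    n: int,
    theta: float,
    locus_length: int,
    reps: int,
    seed: int,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> tuple[float, float]:
    """Empirical null quantiles of a statistic under the standard neutral
    constant-size coalescent, via seeded simulation."""
    from .synthetic_data import simulate_coalescent

    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        sub = int(rng.integers(1, 2**31 - 1))
        _, aln = simulate_coalescent(n, {"theta": theta}, locus_length, sub)
        v = statistic(aln, range(aln.length))
        if math.isfinite(v):
            vals.append(v)
    lo, hi = np.quantile(vals, quantiles)
    return float(lo), float(hi)


def neutrality_summary(
    a: Alignment,
    sites: Sequence[int],
    significance: bool = False,
    null_reps: int = 1000,
    seed: int = 0,
) -> NeutralitySummary:
    """All four neutrality tests, optionally with significance flags from a
    seeded coalescent null (theta matched to the observed k)."""
    S, _, _ = site_classes(a, sites)
    if S == 0:
        nan = float("nan")
        return NeutralitySummary(nan, nan, nan, nan, defined=False)
    D = tajima_D(a, sites)
    Dstar, Fstar = fu_li_tests(a, sites)
    Fs = fu_Fs(a, sites)
    summary = NeutralitySummary(D, Dstar, Fstar, Fs, defined=True)
    if significance:
        k = mean_pairwise_differences(a, sites)
        flags = {}
        for name, stat_fn, value, alpha in (
            ("tajima_D", tajima_D, D, 0.05),
            ("fu_li_Dstar", lambda x, s: fu_li_tests(x, s)[0], Dstar, 0.05),
            ("fu_li_Fstar", lambda x, s: fu_li_tests(x, s)[1], Fstar, 0.05),
            ("fu_Fs", fu_Fs, Fs, 0.04),  # two-sided envelope of the p<0.02 rule
        ):
            lo, hi = simulated_null_quantiles(
                stat_fn, a.n, max(k, 0.1), len(list(sites)), null_reps, seed,
                quantiles=(alpha / 2, 1 - alpha / 2),
            )
            flags[name] = bool(value < lo or value > hi)
        summary.significant = flags
    return summary
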