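"""Synthetic data with the statistical structure the analyses assume.

Generators for:

* Kingman-coalescent samples (constant size or sudden expansion) over a
  finite-sites 628 bp locus, with the genealogy exportable as Newick in
  mutational units — the same model family the mismatch-distribution
  machinery fits;
* multi-breed scenarios: divergent haplogroup founder pools, per-breed
  admixture fractions and per-pool expansion histories, with truth tables
  for recovery tests (the layout mirrors a multi-breed mtDNA survey:
  half a dozen focal breeds of ~30 animals each plus foreign pools);
* climate/genetics table pairs with planted linear effects.

Mutation model: equal-rate finite sites (Jukes-Cantor), no recombination
(mtDNA), no selection.  Everything is bit-reproducible under a fixed seed.

Internal coalescent scaling: the simulator fixes an arbitrary per-locus
per-generation mutation rate U and chooses the population size Ne so that
theta = 2*Ne*U; an expansion at tau mutational units back is placed at
tau/(2U) generations.  Only the theta/tau parameterisation is visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import msprime
import numpy as np

from .seqio import Alignment

__all__ = [
    "ScenarioConfig",
    "BreedSpec",
    "simulate_coalescent",
    "genealogy_newick",
    "simulate_scenario",
    "make_climate_fixture",
    "default_scenario",
]

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
_U_TOTAL = 0.01  # internal per-locus per-generation mutation rate


def _msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 2))


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_coalescent(
    n: int,
    demography: Mapping[str, float],
    locus_length: int = 628,
    seed: int = 1,
) -> tuple["msprime.TreeSequence", Alignment]:
    """Simulate a coalescent sample and its finite-sites alignment.

    ``demography`` is either ``{"theta": x}`` (constant size, E[k] = theta)
    or ``{"theta0": a, "theta1": b, "tau": t}`` (sudden expansion from
    diversity a to b, t mutational units before present).  Returns the
    tree sequence (genealogy) and an :class:`Alignment` with ids s0..s{n-1}.
    """
    rng = np.random.default_rng(seed)
    U = _U_TOTAL
    u_site = U / locus_length
    if "theta" in demography:
        theta_now = float(demography["theta"])
        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=max(theta_now, 1e-8) / (2 * U))
    else:
        theta0 = float(demography["theta0"])
        theta1 = float(demography["theta1"])
        tau = float(demography["tau"])
        theta_now = theta1
        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=max(theta1, 1e-8) / (2 * U))
        dem.add_population_parameters_change(
            time=tau / (2 * U), initial_size=max(theta0, 1e-8) / (2 * U)
        )
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        demography=dem,
        sequence_length=locus_length,
        discrete_genome=True,
        random_seed=_msprime_seed(rng),
    )
    if theta_now > 0:
        ts = msprime.sim_mutations(
            ts,
            rate=u_site,
            model=msprime.JC69(),
            random_seed=_msprime_seed(rng),
        )
    ref = _random_sequence(locus_length, rng)
    M = np.tile(ref, (n, 1))
    for var in ts.variants():
        pos = int(var.site.position)
        alleles = np.array([al.encode() for al in var.alleles], dtype="S1")
        M[:, pos] = alleles[var.genotypes]
    ids = [f"s{i}" for i in range(n)]
    seqs = [bytes(M[i]).decode("ascii") for i in range(n)]
    return ts, Alignment(ids, seqs)


def genealogy_newick(ts: "msprime.TreeSequence") -> str:
    """Newick export of the (single, non-recombining) genealogy with branch
    lengths rescaled to mutational units (expected mutations per branch,
    i.e. generations times the per-locus rate)."""
    tree = ts.first()
    labels = {int(u): f"s{i}" for i, u in enumerate(ts.samples())}

    def render(u: int) -> str:
        children = tree.children(u)
        length = tree.branch_length(u) * _U_TOTAL
        if not children:
            return f"{labels[int(u)]}:{length:.6f}"
        inner = ",".join(render(c) for c in children)
        return f"({inner}):{length:.6f}"

    return render(tree.root) + ";"


@dataclass
class BreedSpec:
    name: str
    region: str
    n: int
    admixture: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("breed sample size must be positive")
        if self.admixture:
            total = sum(self.admixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"admixture fractions for {self.name!r} sum to {total}, not 1"
                )


@dataclass
class ScenarioConfig:
    """Study-design description for :func:`simulate_scenario`.

    ``sources`` maps founder-pool names (haplogroup-like lineages) to
    demographies (as in :func:`simulate_coalescent`); ``divergence`` is
    the number of private founder substitutions separating each pool from
    the shared root sequence.  Each breed draws its individuals from the
    pools according to its admixture fractions.
    """

    breeds: list[BreedSpec]
    sources: dict[str, Mapping[str, float]]
    divergence: int = 15
    locus_length: int = 628
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.breeds or not self.sources:
            raise ValueError("need at least one breed and one source pool")
        for b in self.breeds:
            for s in b.admixture:
                if s not in self.sources:
                    raise ValueError(f"unknown source {s!r} for breed {b.name!r}")


def simulate_scenario(
    config: ScenarioConfig,
) -> tuple[Alignment, dict[str, dict[str, str]], dict[str, dict]]:
    """Simulate a multi-breed, multi-founder sample.

    Returns ``(alignment, metadata, truth)`` where truth records each
    individual's source pool, the founder sequences, and the planted
    per-breed admixture fractions.
    """
    rng = np.random.default_rng(config.seed)
    L = config.locus_length
    source_names = sorted(config.sources)
    root = _random_sequence(L, rng)

    # disjoint private substitution positions per pool
    need = config.divergence * len(source_names)
    if need > L:
        raise ValueError("divergence too large for locus length")
    pos = rng.choice(L, size=need, replace=False)
    founders: dict[str, np.ndarray] = {}
    for i, s in enumerate(source_names):
        f = root.copy()
        for p in pos[i * config.divergence : (i + 1) * config.divergence]:
            current = f[p]
            alt = _BASES[_BASES != current]
            f[p] = rng.choice(alt)
        founders[s] = f

    # assign each individual to a source pool
    assignment: list[tuple[str, str, str]] = []  # (id, breed, source)
    per_source: dict[str, list[str]] = {s: [] for s in source_names}
    for breed in config.breeds:
        adm = breed.admixture or {source_names[0]: 1.0}
        srcs = sorted(adm)
        probs = np.array([adm[s] for s in srcs])
        draws = rng.choice(len(srcs), size=breed.n, p=probs)
        for j, d in enumerate(draws):
            sid = f"{breed.name}_{j:03d}"
            src = srcs[d]
            assignment.append((sid, breed.name, src))
            per_source[src].append(sid)

    # simulate each pool's internal variation, then overlay founder states
    seq_of: dict[str, str] = {}
    for s in source_names:
        members = per_source[s]
        if not members:
            continue
        _, aln = simulate_coalescent(
            len(members), config.sources[s], L, _msprime_seed(rng)
        )
        M = aln.matrix().copy()
        f = founders[s]
        for p in pos:  # founder-defining columns override pool variation
            M[:, p] = f[p]
        for i, sid in enumerate(members):
            seq_of[sid] = bytes(M[i]).decode("ascii")

    ids = [sid for sid, _, _ in assignment]
    seqs = [seq_of[sid] for sid in ids]
    metadata = {
        sid: {"breed": breed, "region": _region_of(config, breed), "haplogroup": src}
        for sid, breed, src in assignment
    }
    truth = {
        "source_of": {sid: src for sid, _, src in assignment},
        "founders": {s: bytes(f).decode("ascii") for s, f in founders.items()},
        "admixture": {
            b.name: dict(b.admixture or {source_names[0]: 1.0})
            for b in config.breeds
        },
    }
    return Alignment(ids, seqs, metadata), metadata, truth


def _region_of(config: ScenarioConfig, breed_name: str) -> str:
    for b in config.breeds:
        if b.name == breed_name:
            return b.region
    raise KeyError(breed_name)


def default_scenario(seed: int = 1) -> ScenarioConfig:
    """A study-like design: six focal (Moroccan) breeds of 29-37 animals,
    foreign Iberian/Italian/Oriental pools, two founder lineages with the
    focal breeds drawing mostly on the western (Iberian-linked) pool."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(29, 38, size=6)
    moroccan = [
        BreedSpec(
            name=f"MOR{i+1}",
            region="Moroccan",
            n=int(sizes[i]),
            admixture={"west": 0.79, "east": 0.21},
        )
        for i in range(6)
    ]
    foreign = [
        BreedSpec("IBE1", "Iberian", 40, {"west": 1.0}),
        BreedSpec("IBE2", "Iberian", 35, {"west": 1.0}),
        BreedSpec("ITA1", "Italian", 40, {"west": 1.0}),
        BreedSpec("ORI1", "Oriental", 35, {"east": 1.0}),
    ]
    return ScenarioConfig(
        breeds=moroccan + foreign,
        sources={
            "west": {"theta0": 0.1, "theta1": 99999.0, "tau": 5.1},
            "east": {"theta0": 0.1, "theta1": 99999.0, "tau": 6.6},
        },
        divergence=15,
        locus_length=628,
        seed=seed,
    )


def planted_admixture_scenario(
    foreign_fraction: float = 0.3, seed: int = 1
) -> ScenarioConfig:
    """A focal breed drawing ``foreign_fraction`` of its founders from a
    foreign pool, flanked by a pure foreign and a pure native breed.

    Pool sizes are balanced (foreign clade ~ native clade) and within-pool
    variation is constant-size coalescent (theta = 3), which keeps the
    reconstructed tree hierarchical rather than star-like, the regime in
    which the terminal-branch affinity share tracks the founder fraction.
    """
    return ScenarioConfig(
        breeds=[
            BreedSpec("X", "focal", 30,
                      {"A": 1.0 - foreign_fraction, "B": foreign_fraction}),
            BreedSpec("Y", "foreign", 40, {"B": 1.0}),
            BreedSpec("Z", "native", 28, {"A": 1.0}),
        ],
        sources={"A": {"theta": 3.0}, "B": {"theta": 3.0}},
        divergence=15,
        locus_length=628,
        seed=seed,
    )


def two_wave_scenario(
    tau_old: float = 9.5, tau_young: float = 6.5, seed: int = 1
) -> ScenarioConfig:
    """Two divergent founder pools with sudden expansions of different ages
    (tau in mutational units), one breed per pool: the planted two-origin
    structure used to validate network partitioning and expansion dating."""
    return ScenarioConfig(
        breeds=[
            BreedSpec("W1", "r1", 40, {"P1": 1.0}),
            BreedSpec("W2", "r2", 40, {"P2": 1.0}),
        ],
        sources={
            "P1": {"theta0": 0.1, "theta1": 99999.0, "tau": tau_old},
            "P2": {"theta0": 0.1, "theta1": 99999.0, "tau": tau_young},
        },
        divergence=15,
        locus_length=628,
        seed=seed,
    )


def make_climate_fixture(
    breeds: Sequence[str],
    effects: Sequence[tuple[str, str, float, float]],
    seed: int = 1,
):
    """Climate and genetic tables with planted linear relationships.

    ``effects`` lists ``(climate_var, genetic_var, slope, noise_sd)``;
    genetic variables not named in any effect are independent noise.
    Climate variables are drawn on realistic scales (altitude in hundreds
    of metres, temperatures in degC, rainfall in hundreds of mm).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    nb = len(breeds)
    climate = pd.DataFrame(
        {
            "Alti": rng.uniform(50, 2000, nb),
            "m": rng.uniform(-5, 12, nb),
            "M": rng.uniform(24, 40, nb),
            "R": rng.uniform(150, 1200, nb),
            "Tmax": rng.uniform(15, 30, nb),
            "Tmin": rng.uniform(2, 16, nb),
        },
        index=list(breeds),
    )
    climate["Q3"] = 3.43 * climate["R"] / (climate["M"] - climate["m"])
    genetic_vars = sorted({gv for _, gv, _, _ in effects}) or ["pi"]
    genetics = pd.DataFrame(
        {gv: rng.normal(0.0, 1.0, nb) for gv in genetic_vars}, index=list(breeds)
    )
    for cv, gv, slope, noise_sd in effects:
        z = (climate[cv] - climate[cv].mean()) / climate[cv].std()
        genetics[gv] = slope * z + rng.normal(0.0, noise_sd, nb)
    return climate, genetics
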