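"""Rejection-ABC inference of historic migration rates from a haplogroup split.

The observation motivating this machinery: a Y-SNP haplogroup present at
substantial frequency in one small, localized population cluster and entirely
absent elsewhere. How much migration between the ancestral populations is
compatible with such a split? Divergence-with-migration scenarios are
simulated under a structured coalescent (binary haplogroup locus, mutation
rate 1e-8 per generation), summary statistics — the number of alleles and the
Nei gene diversity per population at that locus — are compared with the
observed configuration, and the migration-rate draws behind the closest
simulations form the posterior.

Scenarios (sizes fixed to the sampled counts; a generation is 30 years,
population growth 0.005 per generation discounts ancestral sizes):

* ``SA``: carriers' home population SA/C+ (84 sampled chromosomes, 14
  carriers) vs the remaining SA/C- (927, 0 carriers), diverging 400
  generations ago (12,000 years) from an ancestor of size 138.
* ``AA``: SA/C+ vs all non-carriers of both continents pooled (1282),
  diverging 500 generations ago (15,000 years) from an ancestor of 113.
* ``BA``: three populations (84 / 927 / 355); SA/C- and NA/C- join 400
  generations ago into an ancestor of 174, which joins SA/C+ at 500
  generations (joint ancestor 113).
* ``SA-10x`` / ``AA-10x``: ten-fold effective sizes, same sample sizes.

Migration rates get independent uniform [0, 0.2] priors (per ordered
population pair; the reported rate "into" a population sums over sources).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ystrpopgen.diversity import gene_diversity
from ystrpopgen import _abc_kernels as _k

__all__ = [
    "AbcScenario",
    "AbcPosterior",
    "scenario_config",
    "simulate_scenario",
    "simulate_summaries",
    "abc_reject",
    "run_abc",
]

GENERATION_YEARS = 30.0
GROWTH_PER_GENERATION = 0.005
HAPLOGROUP_MUTATION_RATE = 1e-8
MIGRATION_PRIOR = (0.0, 0.2)


@dataclass
class AbcScenario:
    name: str
    population_names: tuple
    sample_sizes: tuple  # chromosomes sampled per extant population
    pop_sizes: tuple  # effective sizes per extant population
    observed_derived: tuple  # haplogroup carriers per population
    merge_times: tuple  # generations, ascending
    merge_target: tuple
    merge_source: tuple
    merge_newsize: tuple
    mutation_rate: float = HAPLOGROUP_MUTATION_RATE
    prior: tuple = MIGRATION_PRIOR

    def __post_init__(self):
        if not 0.0 <= self.prior[0] < self.prior[1]:
            raise ValueError("invalid migration prior bounds")
        if any(t <= 0 for t in self.merge_times):
            raise ValueError("divergence times must be positive")
        # growth-discount consistency: the deepest ancestor must equal the
        # total extant effective size discounted by growth over its depth
        total_extant = sum(self.pop_sizes)
        final_t = self.merge_times[-1]
        final_size = self.merge_newsize[-1]
        expect = total_extant / (1.0 + GROWTH_PER_GENERATION) ** final_t
        if abs(expect - final_size) > max(1.0, 0.01 * final_size):
            raise ValueError(
                f"ancestral size {final_size} inconsistent with growth discount "
                f"{expect:.1f}"
            )

    @property
    def n_pops(self) -> int:
        return len(self.sample_sizes)

    def observed_summaries(self) -> np.ndarray:
        return _summaries(
            np.asarray([self.observed_derived]),
            np.asarray(self.sample_sizes),
        )[0]


def scenario_config(name: str) -> AbcScenario:
    """The named divergence-with-migration scenario with its fixed constants."""
    scale = 1
    base = name
    if name.endswith("-10x"):
        scale = 10
        base = name[:-4]
    if base == "SA":
        return AbcScenario(
            name=name,
            population_names=("SA/C+", "SA/C-"),
            sample_sizes=(84, 927),
            pop_sizes=(84 * scale, 927 * scale),
            observed_derived=(14, 0),
            merge_times=(400.0,),
            merge_target=(0,),
            merge_source=(1,),
            merge_newsize=(138.0 * scale,),
        )
    if base == "AA":
        return AbcScenario(
            name=name,
            population_names=("SA/C+", "SA/C- + NA/C-"),
            sample_sizes=(84, 1282),
            pop_sizes=(84 * scale, 1282 * scale),
            observed_derived=(14, 0),
            merge_times=(500.0,),
            merge_target=(0,),
            merge_source=(1,),
            merge_newsize=(113.0 * scale,),
        )
    if base == "BA" and scale == 1:
        return AbcScenario(
            name=name,
            population_names=("SA/C+", "SA/C-", "NA/C-"),
            sample_sizes=(84, 927, 355),
            pop_sizes=(84, 927, 355),
            observed_derived=(14, 0, 0),
            merge_times=(400.0, 500.0),
            merge_target=(1, 0),
            merge_source=(2, 1),
            merge_newsize=(174.0, 113.0),
        )
    raise ValueError(f"unknown scenario {name!r}")


def _summaries(derived: np.ndarray, sample_sizes: np.ndarray) -> np.ndarray:
    """(n_sims, 2K) array: per population, number of alleles then Nei
    gene diversity at the haplogroup locus."""
    n_sims, K = derived.shape
    out = np.zeros((n_sims, 2 * K))
    for p in range(K):
        n = int(sample_sizes[p])
        d = derived[:, p].astype(float)
        poly = (d > 0) & (d < n)
        out[:, 2 * p] = np.where(poly, 2.0, 1.0)
        pfreq = d / n
        h = n / (n - 1.0) * (1.0 - pfreq**2 - (1.0 - pfreq) ** 2)
        out[:, 2 * p + 1] = np.where(poly, h, 0.0)
    return out


def _mig_matrix(scenario: AbcScenario, rates: np.ndarray) -> np.ndarray:
    """Expand per-ordered-pair rate draws into (n_sims, K, K) matrices."""
    K = scenario.n_pops
    pairs = [(i, j) for i in range(K) for j in range(K) if i != j]
    if rates.shape[1] != len(pairs):
        raise ValueError(f"expected {len(pairs)} rates per draw")
    out = np.zeros((rates.shape[0], K, K))
    for c, (i, j) in enumerate(pairs):
        out[:, i, j] = rates[:, c]
    return out


def rate_pair_names(scenario: AbcScenario):
    K = scenario.n_pops
    names = scenario.population_names
    return [
        f"into {names[i]} from {names[j]}"
        for i in range(K)
        for j in range(K)
        if i != j
    ]


def simulate_summaries(
    scenario: AbcScenario, migration_rates: np.ndarray, seed: int
) -> np.ndarray:
    """Simulate one dataset per row of *migration_rates* (per-ordered-pair
    backward rates); returns the (n_sims, 2K) summary-statistic array."""
    rates = np.atleast_2d(np.asarray(migration_rates, dtype=float))
    if np.any(rates < 0) or np.any(rates >= 1):
        raise ValueError("migration rates must lie in [0, 1)")
    mig = _mig_matrix(scenario, rates)
    derived = np.zeros((rates.shape[0], scenario.n_pops), dtype=np.int64)
    _k.simulate_batch(
        scenario.n_pops,
        np.asarray(scenario.sample_sizes, dtype=np.int64),
        np.asarray(scenario.pop_sizes, dtype=np.float64),
        np.asarray(scenario.merge_times, dtype=np.float64),
        np.asarray(scenario.merge_target, dtype=np.int64),
        np.asarray(scenario.merge_source, dtype=np.int64),
        np.asarray(scenario.merge_newsize, dtype=np.float64),
        mig,
        float(scenario.mutation_rate),
        int(seed) % (2**32 - 1),
        derived,
    )
    return _summaries(derived, np.asarray(scenario.sample_sizes))


def simulate_scenario(scenario: AbcScenario, migration_rates, seed: int = 0):
    """Single simulation; returns per-population (n_alleles, gene_diversity)."""
    s = simulate_summaries(scenario, np.atleast_2d(migration_rates), seed)[0]
    K = scenario.n_pops
    return [(int(s[2 * p]), float(s[2 * p + 1])) for p in range(K)]


@dataclass
class AbcPosterior:
    parameter_names: list
    accepted: np.ndarray  # (n_accept, n_params)
    distances: np.ndarray
    n_simulations: int
    medians: dict = field(init=False)
    iqr: dict = field(init=False)

    def __post_init__(self):
        self.medians = {}
        self.iqr = {}
        for c, name in enumerate(self.parameter_names):
            q1, med, q3 = np.percentile(self.accepted[:, c], [25, 50, 75])
            self.medians[name] = float(med)
            self.iqr[name] = (float(q1), float(q3))


def abc_reject(
    observed: np.ndarray,
    params: np.ndarray,
    summaries: np.ndarray,
    n_accept: int,
    parameter_names=None,
) -> AbcPosterior:
    """Keep the *n_accept* parameter draws whose summaries are closest to the
    observation in standardized Euclidean distance.

    Each summary dimension is scaled by its standard deviation across all
    simulations; degenerate (constant) dimensions are dropped with a warning.
    Ties are broken by simulation index.
    """
    import logging

    params = np.atleast_2d(np.asarray(params, dtype=float))
    summaries = np.asarray(summaries, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if n_accept > summaries.shape[0]:
        raise ValueError("n_accept exceeds the number of simulations")
    sd = summaries.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logging.getLogger(__name__).warning(
            "dropping %d degenerate summary dimensions", int((~keep).sum())
        )
    if not keep.any():
        # no simulation produced any variation: nothing discriminates the
        # draws, so the "posterior" is the prior (ties broken by index)
        logging.getLogger(__name__).warning(
            "all summary dimensions degenerate; accepted draws carry no information"
        )
        dist = np.zeros(summaries.shape[0])
    else:
        z = (summaries[:, keep] - observed[keep]) / sd[keep]
        dist = np.sqrt(np.sum(z * z, axis=1))
    order = np.lexsort((np.arange(len(dist)), dist))[:n_accept]
    if parameter_names is None:
        parameter_names = [f"param_{i}" for i in range(params.shape[1])]
    return AbcPosterior(
        parameter_names=list(parameter_names),
        accepted=params[order],
        distances=dist[order],
        n_simulations=summaries.shape[0],
    )


def run_abc(
    scenario: AbcScenario,
    n_simulations: int = 1_000_000,
    n_accept: int = 100,
    seed: int = 0,
) -> AbcPosterior:
    """Full rejection-ABC run for a scenario: draw migration rates from the
    uniform prior, simulate, and keep the closest *n_accept* draws.

    Posterior columns are per-ordered-pair rates followed by the aggregated
    rates into each population (sum over sources).
    """
    rng = np.random.default_rng(seed)
    K = scenario.n_pops
    n_pairs = K * (K - 1)
    lo, hi = scenario.prior
    rates = rng.uniform(lo, hi, size=(n_simulations, n_pairs))
    summaries = simulate_summaries(
        scenario, rates, seed=int(rng.integers(1, 2**31 - 1))
    )
    names = rate_pair_names(scenario)
    # aggregate rate into each population
    into = np.zeros((n_simulations, K))
    pairs = [(i, j) for i in range(K) for j in range(K) if i != j]
    for c, (i, j) in enumerate(pairs):
        into[:, i] += rates[:, c]
    params = np.hstack([rates, into])
    names = names + [f"into {nm}" for nm in scenario.population_names]
    return abc_reject(
        scenario.observed_summaries(), params, summaries, n_accept, names
    )
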