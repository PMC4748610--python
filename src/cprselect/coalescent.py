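"""Coalescent null model for Tajima's D outlier calling.

The demographic scenario the statistic is tested against is an
African-bottleneck / European-growth / North-American-admixture history:
the ancestral African population experiences a bottleneck, Europe is founded
from Africa and grows exponentially, and the sampled population arises as an
admixture of the two.  The actual parameter values of that history are
config inputs; :func:`toy_admixture_model` provides a clearly-labelled
placeholder parameterization for structural testing only, and
:func:`constant_model` the standard constant-size neutral null.

Simulation is delegated to msprime (haploid samples, infinite-sites
mutations); observed D values are converted to two-tailed empirical P values
against the simulated distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np

from .alignment import CprAlignment
from .popgen import tajimas_d

__all__ = [
    "Deme",
    "DemographicEvent",
    "DemographicModel",
    "NullDistribution",
    "constant_model",
    "toy_admixture_model",
    "simulate_sample",
    "build_null",
    "outlier_pvalue",
]

#: per-generation mutation rate per bp (D. melanogaster estimate)
DEFAULT_MU = 1.45e-9
#: recombination rate in cM per bp (D. melanogaster estimate)
DEFAULT_REC_CM_PER_BP = 5.0e-7


@dataclass
class Deme:
    name: str
    initial_size: float  # in units of N_ref (diploid-equivalent scaling)
    growth_rate: float = 0.0  # per generation, exponential


@dataclass
class DemographicEvent:
    """A backwards-in-time demographic event.

    kind:
      * ``size_change`` — deme's size (units of N_ref) and/or growth rate
        change at ``time``;
      * ``founding`` — ``deme`` was founded from ``sources[0]`` at ``time``
        (backwards: its lineages move to the source);
      * ``admixture`` — ``deme`` arose at ``time`` as a mixture of
        ``sources`` with ``proportions`` (summing to 1).
    Times are in generations before present, strictly increasing.
    """

    kind: str
    time: float
    deme: str
    size: float | None = None
    growth_rate: float | None = None
    sources: tuple[str, ...] = ()
    proportions: tuple[float, ...] = ()


@dataclass
class DemographicModel:
    demes: list[Deme]
    events: list[DemographicEvent] = field(default_factory=list)
    mu: float = DEFAULT_MU
    rec_cm_per_bp: float = DEFAULT_REC_CM_PER_BP
    N_ref: float = 1e6
    sample_deme: str | None = None  # default: first deme

    def __post_init__(self) -> None:
        if self.mu < 0 or self.rec_cm_per_bp < 0:
            raise ValueError("rates must be >= 0")
        names = [d.name for d in self.demes]
        if len(set(names)) != len(names):
            raise ValueError("deme names must be unique")
        for d in self.demes:
            if d.initial_size <= 0:
                raise ValueError(f"non-positive size for deme {d.name}")
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be ordered backwards in time")
        for e in self.events:
            if e.kind == "admixture":
                if not math.isclose(sum(e.proportions), 1.0):
                    raise ValueError("admixture proportions must sum to 1")
            if e.kind == "size_change" and e.size is not None and e.size <= 0:
                raise ValueError("non-positive deme size")

    @property
    def rec_per_bp(self) -> float:
        """Crossover probability per bp per generation (1 cM = 0.01)."""
        return self.rec_cm_per_bp * 0.01

    def to_demography(self):
        """Translate to an msprime.Demography (haploid-sample ready).

        Samples are haploid (inbred lines), and msprime's pairwise
        coalescence rate with ploidy=1 is 1/size, so sizes are passed as
        2 * N_ref * scaled_size to keep the diploid convention
        theta = 4 * N_ref * mu (E[T2] = 2 N_ref generations).
        """
        import msprime

        dem = msprime.Demography()
        for d in self.demes:
            dem.add_population(
                name=d.name,
                initial_size=2.0 * d.initial_size * self.N_ref,
                growth_rate=d.growth_rate,
                initially_active=True,
            )
        for e in self.events:
            if e.kind == "size_change":
                dem.add_population_parameters_change(
                    time=e.time,
                    population=e.deme,
                    initial_size=None if e.size is None else 2.0 * e.size * self.N_ref,
                    growth_rate=e.growth_rate,
                )
            elif e.kind == "founding":
                dem.add_mass_migration(
                    time=e.time, source=e.deme, dest=e.sources[0], proportion=1.0
                )
            elif e.kind == "admixture":
                # backwards in time each lineage of `deme` picks a source;
                # sequential mass migrations with renormalized proportions
                remaining = 1.0
                for src, p in zip(e.sources[:-1], e.proportions[:-1]):
                    dem.add_mass_migration(
                        time=e.time, source=e.deme, dest=src, proportion=p / remaining
                    )
                    remaining -= p
                dem.add_mass_migration(
                    time=e.time, source=e.deme, dest=e.sources[-1], proportion=1.0
                )
            else:
                raise ValueError(f"unknown event kind {e.kind!r}")
        dem.sort_events()
        return dem


def constant_model(
    N: float = 1e6, mu: float = DEFAULT_MU, rec_cm_per_bp: float = DEFAULT_REC_CM_PER_BP
) -> DemographicModel:
    """Single constant-size deme: the standard neutral null."""
    return DemographicModel(
        demes=[Deme("pop", 1.0)], mu=mu, rec_cm_per_bp=rec_cm_per_bp, N_ref=N
    )


def toy_admixture_model(N_ref: float = 1e6) -> DemographicModel:
    """Placeholder bottleneck/growth/admixture history (NOT estimated values).

    Structure: the sampled population is an admixture of an African deme
    (which underwent an older bottleneck) and a European deme founded from
    Africa that then grew exponentially.  The sizes, times and admixture
    proportion below are toy placeholders for exercising the machinery; any
    real analysis must supply parameters estimated for its own population.
    """
    growth = math.log(10.0) / 4.1e4  # Europe grew 10x since its founding
    return DemographicModel(
        demes=[
            Deme("america", 1.0),
            Deme("europe", 0.2, growth_rate=growth),
            Deme("africa", 1.0),
        ],
        events=[
            DemographicEvent(
                "admixture", 1e3, "america",
                sources=("africa", "europe"), proportions=(0.15, 0.85),
            ),
            DemographicEvent("founding", 4.1e4, "europe", sources=("africa",)),
            DemographicEvent("size_change", 4.2e4, "africa", size=0.1),  # bottleneck
            DemographicEvent("size_change", 5.0e4, "africa", size=1.0),
        ],
        N_ref=N_ref,
        sample_deme="america",
    )


_BASES = np.array(["A", "C", "G", "T"], dtype="<U1")


def _ts_to_alignment(ts, L: int, cpr_id: str, rng: np.random.Generator) -> CprAlignment:
    """Map an infinite-sites tree sequence to an L-bp character alignment.

    Continuous mutation positions are assigned distinct integer columns
    (floor position, shifted right to the next free column on collision), so
    every segregating site occupies its own column and column patterns match
    the genealogy exactly.
    """
    n = ts.num_samples
    ref = _BASES[rng.integers(0, 4, size=L)]
    seqs = np.tile(ref, (n, 1))
    used: set[int] = set()
    for var in ts.variants():
        col = int(var.site.position)
        while col in used:
            col += 1
        if col >= L:  # wrap to leftmost free column
            col = 0
            while col in used:
                col += 1
            if col >= L:
                raise ValueError("more segregating sites than alignment columns")
        used.add(col)
        anc = ref[col]
        derived = _BASES[(int(np.flatnonzero(_BASES == anc)[0]) + 1 + rng.integers(0, 3)) % 4]
        carriers = np.asarray(var.genotypes) > 0
        seqs[carriers, col] = derived
    lines = [f"line{i:03d}" for i in range(n)]
    return CprAlignment(
        cpr_id=cpr_id, chrom="sim", start=0, end=L, strand="+", line_ids=lines, seqs=seqs
    )


def _sim_ancestry_kwargs(model: DemographicModel, n: int, L: int) -> dict:
    import msprime

    dem = model.to_demography()
    deme = model.sample_deme or model.demes[0].name
    return dict(
        samples={deme: n},
        demography=dem,
        ploidy=1,
        sequence_length=L,
        recombination_rate=model.rec_per_bp,
        discrete_genome=False,
    )


def simulate_sample(
    model: DemographicModel, n: int, L: int, seed: int | None = None, cpr_id: str = "sim"
) -> CprAlignment:
    """Draw one n-haplotype, L-bp sample under the demographic model.

    Backward-in-time coalescent with recombination; infinite-sites mutations
    at rate theta/2 per lineage (theta = 4*N_ref*mu*L overall).
    """
    import msprime

    if n < 1 or L < 1:
        raise ValueError("n >= 1 and L >= 1 required")
    ss = np.random.SeedSequence(seed)
    s_anc, s_mut, s_map = (int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(3))
    ts = msprime.sim_ancestry(random_seed=s_anc, **_sim_ancestry_kwargs(model, n, L))
    ts = msprime.sim_mutations(
        ts, rate=model.mu, random_seed=s_mut, discrete_genome=False
    )
    return _ts_to_alignment(ts, L, cpr_id, np.random.default_rng(s_map))


@dataclass
class NullDistribution:
    """Simulated Tajima's D values under a demographic null."""

    model: DemographicModel
    n: int
    L: int
    reps: int
    d_values: np.ndarray  # finite D values only
    n_monomorphic: int  # runs with S = 0 (D undefined)
    seed: int | None

    def __post_init__(self) -> None:
        if len(self.d_values) + self.n_monomorphic != self.reps:
            raise ValueError("d_values + monomorphic runs must equal reps")

    @property
    def median(self) -> float:
        return float(np.median(self.d_values))


def build_null(
    model: DemographicModel,
    n: int = 29,
    L: int = 160,
    reps: int = 100_000,
    seed: int | None = None,
) -> NullDistribution:
    """Simulate ``reps`` samples and collect the Tajima's D null distribution.

    D is computed with the same statistic implementation applied to observed
    CPRs; monomorphic replicates (S = 0, D undefined) are excluded from the
    distribution and counted separately.
    """
    import msprime

    if reps < 1:
        raise ValueError("reps >= 1 required")
    ss = np.random.SeedSequence(seed)
    s_anc, s_mut, s_map = (int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(3))
    rng_map = np.random.default_rng(s_map)
    reps_iter = msprime.sim_ancestry(
        random_seed=s_anc, num_replicates=reps, **_sim_ancestry_kwargs(model, n, L)
    )
    mut_rng = np.random.default_rng(s_mut)
    d_values: list[float] = []
    n_mono = 0
    for i, ts in enumerate(reps_iter):
        mts = msprime.sim_mutations(
            ts,
            rate=model.mu,
            random_seed=int(mut_rng.integers(1, 2**31 - 1)),
            discrete_genome=False,
        )
        if mts.num_sites == 0:
            n_mono += 1
            continue
        aln = _ts_to_alignment(mts, L, f"rep{i}", rng_map)
        d = tajimas_d(aln)
        if math.isnan(d):
            n_mono += 1
        else:
            d_values.append(d)
    return NullDistribution(
        model=model,
        n=n,
        L=L,
        reps=reps,
        d_values=np.asarray(d_values),
        n_monomorphic=n_mono,
        seed=seed,
    )


def outlier_pvalue(d_obs: float, null: NullDistribution) -> tuple[float, str]:
    """Two-tailed empirical P for an observed D against the null.

    p_upper = (#{D_sim >= d_obs} + 1) / (R + 1), p_lower symmetric,
    P = min(1, 2 * min(p_upper, p_lower)); the +1 correction avoids P = 0
    from a finite simulation.  Verdict: "balancing-candidate" if P < 0.01 and
    d_obs lies above the null median, "purifying/sweep-candidate" if below,
    else "not significant".
    """
    d = null.d_values
    R = len(d)
    if R == 0:
        raise ValueError("null distribution has no usable D values")
    p_upper = (int(np.sum(d >= d_obs)) + 1) / (R + 1)
    p_lower = (int(np.sum(d <= d_obs)) + 1) / (R + 1)
    p = min(1.0, 2.0 * min(p_upper, p_lower))
    if p < 0.01:
        verdict = "balancing-candidate" if d_obs > null.median else "purifying/sweep-candidate"
    else:
        verdict = "not significant"
    return p, verdict
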