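"""Coalescent and sweep simulation of the fitted Han-Tibetan demography.

The demographic model is the two-population ∂a∂i fit consumed as constants
(diploid sizes nA1, nC1..nC3, nT1..nT3; epoch bounds T1, T2, T3 in years;
per-generation per-chromosome migration rates m11, m12, m21, m22). Reading
of the size history: the split ``T2 + T3`` years ago founds the Han lineage
at nC1 and the Tibetan lineage at nT1; each grows exponentially to
(nC2, nT2) by T3 years ago and on to (nC3, nT3) by T1 years ago, constant
since. Migration runs at (m11, m12) between the split and T3 years ago and
drops to (m21, m22) afterwards. This reading reproduces the model-predicted
genome-wide Hudson F_ST of ~0.0147 between 27 Tibetan and 62 Han diploids.

Neutral and archaic-admixture scenarios are simulated with msprime;
selective sweeps use a conditioned Wright-Fisher frequency bridge plus a
forward haplotype-copying phase on top of an msprime neutral panel (msprime
cannot condition a sweep on both its onset time and its end frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd
import tskit

from .data_model import HaplotypePanel, SiteFrequencyTable, site_frequency_table

__all__ = [
    "TABLE1",
    "DemographicModel",
    "ArchaicScenario",
    "AdmixturePulse",
    "SweepScenario",
    "SweepRealization",
    "UnattainableSweepError",
    "build_model",
    "simulate_neutral",
    "simulate_sweep",
    "simulate_archaic",
    "sweep_frequency_trajectory",
    "sweep_grid",
    "SWEEP_GRID_S",
    "SWEEP_GRID_ONSETS",
    "SWEEP_GRID_END_FREQS",
]

#: Point estimates of the fitted two-population demographic model.
TABLE1: dict[str, float] = {
    "nA1": 12804.0,
    "nC1": 500.0,
    "nC2": 75203.0,
    "nC3": 1326988.0,
    "nT1": 2445.0,
    "nT2": 13292.0,
    "nT3": 77743.0,
    "T1": 6355.0,
    "T2": 44588.0,
    "T3": 9419.0,
    "m11": 6.8e-4,
    "m12": 9.0e-4,
    "m21": 1.3e-11,
    "m22": 4.0e-7,
}

TARGET = "TIB"
COMPARISON = "HAN"


class UnattainableSweepError(ValueError):
    """The requested end frequency cannot be reached for the given s/onset."""


@dataclass
class DemographicModel:
    """Two-population model with exponential-growth epochs.

    All sizes are diploid; times are years ago; migration rates are
    per generation per chromosome (forward-time fractions).
    """

    nA1: float = TABLE1["nA1"]
    nC1: float = TABLE1["nC1"]
    nC2: float = TABLE1["nC2"]
    nC3: float = TABLE1["nC3"]
    nT1: float = TABLE1["nT1"]
    nT2: float = TABLE1["nT2"]
    nT3: float = TABLE1["nT3"]
    T1: float = TABLE1["T1"]
    T2: float = TABLE1["T2"]
    T3: float = TABLE1["T3"]
    m11: float = TABLE1["m11"]  # Tibetan -> Han, before T3 years ago
    m12: float = TABLE1["m12"]  # Han -> Tibetan, before T3 years ago
    m21: float = TABLE1["m21"]  # Tibetan -> Han, after T3 years ago
    m22: float = TABLE1["m22"]  # Han -> Tibetan, after T3 years ago
    generation_time: float = 25.0  # years/generation
    mutation_rate: float = 1.25e-8  # per bp per generation
    recombination_rate: float = 1e-8  # per bp per generation

    def __post_init__(self) -> None:
        for name in ("nA1", "nC1", "nC2", "nC3", "nT1", "nT2", "nT3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"population size {name} must be positive")
        for name in ("m11", "m12", "m21", "m22"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"migration rate {name} must be in [0, 1)")
        if not 0 < self.T1 < self.T3:
            raise ValueError("epoch bounds must satisfy 0 < T1 < T3")
        if self.T2 <= 0:
            raise ValueError("T2 must be positive")

    @property
    def divergence_time_years(self) -> float:
        """Han-Tibetan split, exactly T2 + T3 years ago."""
        return self.T2 + self.T3

    # -- conversions ----------------------------------------------------
    def years_to_generations(self, years: float) -> float:
        return years / self.generation_time

    def epoch_bounds_generations(self) -> tuple[float, float, float]:
        g = self.generation_time
        return self.T1 / g, self.T3 / g, (self.T2 + self.T3) / g

    def population_size_at(self, population: str, generations_ago: np.ndarray) -> np.ndarray:
        """Diploid size of ``population`` at each time (generations ago).

        Beyond the split the ancestral size nA1 applies.
        """
        t = np.asarray(generations_ago, dtype=float)
        t1, t3, tdiv = self.epoch_bounds_generations()
        if population == COMPARISON:
            n1, n2, n3 = self.nC1, self.nC2, self.nC3
        elif population == TARGET:
            n1, n2, n3 = self.nT1, self.nT2, self.nT3
        else:
            raise KeyError(population)
        out = np.full(t.shape, float(self.nA1))
        recent = t < t1
        mid = (t >= t1) & (t < t3)
        old = (t >= t3) & (t < tdiv)
        out[recent] = n3
        with np.errstate(over="ignore"):
            out[mid] = n3 * (n2 / n3) ** ((t[mid] - t1) / (t3 - t1))
            out[old] = n2 * (n1 / n2) ** ((t[old] - t3) / (tdiv - t3))
        return out

    # -- msprime --------------------------------------------------------
    def to_msprime(self) -> msprime.Demography:
        t1, t3, tdiv = self.epoch_bounds_generations()
        d = msprime.Demography()
        g_c2 = np.log(self.nC3 / self.nC2) / (t3 - t1)
        g_t2 = np.log(self.nT3 / self.nT2) / (t3 - t1)
        g_c1 = np.log(self.nC2 / self.nC1) / (tdiv - t3)
        g_t1 = np.log(self.nT2 / self.nT1) / (tdiv - t3)
        d.add_population(name=COMPARISON, initial_size=self.nC3)
        d.add_population(name=TARGET, initial_size=self.nT3)
        d.add_population(name="ANC", initial_size=self.nA1)
        # Forward-time migration X->Y is the backward rate of lineages in Y
        # moving to X.
        d.set_migration_rate(source=COMPARISON, dest=TARGET, rate=self.m21)
        d.set_migration_rate(source=TARGET, dest=COMPARISON, rate=self.m22)
        d.add_population_parameters_change(
            time=t1, population=COMPARISON, initial_size=self.nC3, growth_rate=g_c2
        )
        d.add_population_parameters_change(
            time=t1, population=TARGET, initial_size=self.nT3, growth_rate=g_t2
        )
        d.add_population_parameters_change(
            time=t3, population=COMPARISON, initial_size=self.nC2, growth_rate=g_c1
        )
        d.add_population_parameters_change(
            time=t3, population=TARGET, initial_size=self.nT2, growth_rate=g_t1
        )
        d.add_migration_rate_change(time=t3, source=COMPARISON, dest=TARGET, rate=self.m11)
        d.add_migration_rate_change(time=t3, source=TARGET, dest=COMPARISON, rate=self.m12)
        d.add_population_split(time=tdiv, derived=[COMPARISON, TARGET], ancestral="ANC")
        d.sort_events()
        return d


def build_model(**overrides: float) -> DemographicModel:
    """Model from the fitted point estimates, with keyword overrides."""
    return DemographicModel(**overrides)


@dataclass
class AdmixturePulse:
    time_years: float
    source: str  # archaic branch label: "DENI" or "NEA"
    destination: str  # modern population label
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("pulse fraction must be in [0, 1]")


@dataclass
class ArchaicScenario:
    """Archaic branches and admixture pulses layered onto the modern model.

    The sampled Denisovan ("DEN") and the introgressing Denisovan-like
    branch ("DENI") split ``sampled_vs_introgressor_split_years`` ago; the
    Denisovan stem and Neanderthal ("NEA") split ``denisovan_neanderthal_
    split_years`` ago; all archaics split from moderns
    ``archaic_split_years`` ago. Defaults bracket the published ranges: a
    2% Neanderthal pulse at 55 kya into both modern populations and a 0.4%
    Denisovan pulse at 40 kya into both.
    """

    archaic_split_years: float = 700_000.0
    sampled_vs_introgressor_split_years: float = 400_000.0
    denisovan_neanderthal_split_years: float = 450_000.0
    archaic_size: float = 2500.0
    # the Neanderthal pulse at 55 kya predates the 54 kya split, so it goes
    # into the common ancestor; the Denisovan pulses at 40 kya are post-split
    pulses: list[AdmixturePulse] = field(default_factory=lambda: [
        AdmixturePulse(55_000.0, "NEA", "ANC", 0.02),
        AdmixturePulse(40_000.0, "DENI", COMPARISON, 0.004),
        AdmixturePulse(40_000.0, "DENI", TARGET, 0.004),
    ])

    def validate(self, model: DemographicModel) -> None:
        if not (self.sampled_vs_introgressor_split_years
                < self.denisovan_neanderthal_split_years
                < self.archaic_split_years):
            raise ValueError("archaic split times must be nested")
        tdiv = model.divergence_time_years
        for p in self.pulses:
            if p.source == "DENI" and p.time_years >= self.sampled_vs_introgressor_split_years:
                raise ValueError("Denisovan pulse older than the introgressor split")
            if p.source == "NEA" and p.time_years >= self.denisovan_neanderthal_split_years:
                raise ValueError("Neanderthal pulse older than the Neanderthal split")
            if p.destination == "ANC" and p.time_years < tdiv:
                raise ValueError(
                    "pulse into the common ancestor must predate the divergence"
                )
            if p.destination in (TARGET, COMPARISON) and p.time_years >= tdiv:
                raise ValueError(
                    f"pulse at {p.time_years:.0f} years predates the "
                    f"population split; direct it into 'ANC'"
                )

    def with_fractions(self, m_d: float, m_n: float) -> "ArchaicScenario":
        """Copy of the scenario with all DENI pulses at ``m_d`` and all NEA
        pulses at ``m_n``."""
        pulses = [
            replace(p, fraction=m_d if p.source == "DENI" else m_n) for p in self.pulses
        ]
        return replace(self, pulses=pulses)


@dataclass
class SweepScenario:
    """A selective sweep in one population.

    ``onset_generations_ago`` is when selection began; the derived allele
    reaches ``end_frequency`` at sampling time. When the end frequency is
    not reachable from a single de novo copy within the onset time under
    logistic growth at coefficient ``s``, the sweep starts from standing
    variation at the back-solved logistic frequency (``de_novo=True``
    raises :class:`UnattainableSweepError` instead).
    """

    s: float
    onset_generations_ago: int
    end_frequency: float
    population: str = TARGET
    position: float | None = None  # defaults to the sequence midpoint
    panel_size: int = 1000  # forward-phase haplotype panel for the swept pop
    de_novo: bool = False
    frequency_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0.0 < self.end_frequency < 1.0:
            raise ValueError("end frequency must be in (0, 1)")
        if self.onset_generations_ago < 0:
            raise ValueError("onset must be >= 0 generations ago")


#: The simulated sweep-scenario grid used to train the composite score:
#: 3 selection coefficients x 5 onsets x 4 end frequencies = 60 cells.
SWEEP_GRID_S = (0.02, 0.03, 0.04)
SWEEP_GRID_ONSETS = (0, 100, 200, 300, 400)
SWEEP_GRID_END_FREQS = (0.2, 0.4, 0.6, 0.8)


def sweep_grid() -> list[SweepScenario]:
    return [
        SweepScenario(s=s, onset_generations_ago=t, end_frequency=f)
        for s in SWEEP_GRID_S
        for t in SWEEP_GRID_ONSETS
        for f in SWEEP_GRID_END_FREQS
    ]


# ---------------------------------------------------------------------------
# Panel construction from tree sequences
# ---------------------------------------------------------------------------


def _panel_from_ts(
    ts: tskit.TreeSequence,
    sample_pops: list[str],
    chromosome: str,
    keep_pops: set[str] | None = None,
) -> tuple[HaplotypePanel, np.ndarray]:
    """Build a HaplotypePanel from sampled haplotypes; returns the panel and
    the per-column sample node ids retained (for archaic track extraction
    the caller handles archaic samples separately)."""
    G = ts.genotype_matrix()  # (sites, samples)
    positions = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    # msprime can place several mutations at the same integer position on
    # fine continuous coordinates; keep the first of each integer position
    # so panel positions stay strictly increasing.
    keep_sites = np.concatenate(([True], np.diff(positions) > 0)) if len(positions) else np.array([], bool)
    G = G[keep_sites]
    positions = positions[keep_sites]

    node_pop = np.array(
        [ts.population(ts.node(u).population).metadata.get("name", str(ts.node(u).population))
         for u in ts.samples()]
    )
    node_ind = np.array([ts.node(u).individual for u in ts.samples()])
    cols = np.arange(ts.num_samples)
    if keep_pops is not None:
        sel = np.isin(node_pop, list(keep_pops))
        cols = cols[sel]
    hap_pops = node_pop[cols]
    hap_inds = np.array([f"{p}_{i}" for p, i in zip(hap_pops, node_ind[cols])])
    ind_pops = {ind: pop for ind, pop in zip(hap_inds, hap_pops)}
    panel = HaplotypePanel(
        chromosome=chromosome,
        positions=positions,
        alleles=np.ascontiguousarray(G[:, cols].T.astype(np.int8)),
        haplotype_individuals=hap_inds,
        individual_populations=ind_pops,
    )
    return panel, keep_sites


def _sim(
    demography: msprime.Demography,
    samples: dict[str, int],
    sequence_length: float,
    model_params: DemographicModel,
    rng: np.random.Generator,
) -> tskit.TreeSequence:
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=sequence_length,
        recombination_rate=model_params.recombination_rate,
        random_seed=int(anc_seed),
    )
    return msprime.sim_mutations(
        ts,
        rate=model_params.mutation_rate,
        random_seed=int(mut_seed),
        model=msprime.BinaryMutationModel(),
    )


def simulate_neutral(
    model: DemographicModel,
    samples: dict[str, int] | None = None,
    sequence_length: float = 1_000_000.0,
    seed: int | None = None,
    chromosome: str = "1",
) -> HaplotypePanel:
    """Phased neutral panel under the two-population model.

    ``samples`` gives diploid counts per population (default 27 Tibetan +
    62 Han, the study's sample sizes). The ancestral allele is known by
    construction (0).
    """
    if sequence_length <= 0:
        raise ValueError("sequence length must be positive")
    samples = dict(samples or {TARGET: 27, COMPARISON: 62})
    rng = np.random.default_rng(seed)
    ts = _sim(model.to_msprime(), samples, sequence_length, model, rng)
    panel, _ = _panel_from_ts(ts, list(samples), chromosome)
    return panel


# ---------------------------------------------------------------------------
# Sweep machinery
# ---------------------------------------------------------------------------


def _logistic_start_frequency(s: float, onset: int, end_frequency: float) -> float:
    """Frequency a deterministic logistic path must start from to reach
    ``end_frequency`` in ``onset`` generations."""
    if onset == 0 or s == 0.0:
        return end_frequency
    f = end_frequency
    return f / (f + (1.0 - f) * np.exp(s * onset))


def sweep_frequency_trajectory(
    model: DemographicModel,
    scenario: SweepScenario,
    rng: np.random.Generator,
    batch: int = 512,
    max_batches: int = 400,
) -> np.ndarray:
    """Wright-Fisher frequency path of the selected allele, forward in time
    from onset to the present, conditioned (by rejection) on ending within
    ``frequency_tolerance`` of the requested end frequency.

    Returns the accepted path as an array of length ``onset + 1`` with
    entry 0 at onset and the last entry at sampling time.
    """
    G = scenario.onset_generations_ago
    f = scenario.end_frequency
    gens_ago = np.arange(G, -1, -1, dtype=float)  # forward ordering
    N = model.population_size_at(scenario.population, gens_ago)
    two_n = np.maximum(2, np.round(2 * N).astype(np.int64))
    x_denovo = 1.0 / two_n[0]
    x0 = max(_logistic_start_frequency(scenario.s, G, f), x_denovo)
    if scenario.de_novo:
        if _logistic_start_frequency(scenario.s, G, f) > x_denovo:
            raise UnattainableSweepError(
                f"end frequency {f} unreachable from a de novo copy in "
                f"{G} generations at s={scenario.s}"
            )
        x0 = x_denovo
    if G == 0:
        return np.array([f])
    tol = scenario.frequency_tolerance
    s = scenario.s

    def _logistic_forward(x: np.ndarray, gens: int) -> np.ndarray:
        # deterministic genic-selection trajectory, closed form
        if s == 0.0 or gens == 0:
            return x
        w = np.exp(s * gens)
        return x * w / (1.0 - x + x * w)

    for _ in range(max_batches):
        x = np.full(batch, x0)
        paths = np.empty((batch, G + 1))
        paths[:, 0] = x
        for g in range(1, G + 1):
            remaining = G - g + 1
            xsel = x * (1.0 + s) / (1.0 + s * x)
            # bridging drift: pull the mean so the deterministic remainder
            # of the path ends at the requested frequency
            pull = (f - _logistic_forward(x, remaining)) / remaining
            mean = np.clip(xsel + pull, 0.0, 1.0)
            x = rng.binomial(two_n[g], mean) / two_n[g]
            paths[:, g] = x
        ok = np.abs(paths[:, -1] - f) <= tol
        if ok.any():
            return paths[np.flatnonzero(ok)[0]]
    raise UnattainableSweepError(
        f"no conditioned trajectory found for s={scenario.s}, onset={G}, "
        f"end frequency {f} (tolerance {tol})"
    )


@dataclass
class SweepRealization:
    position: int
    realized_frequency: float
    start_frequency: float
    trajectory: np.ndarray
    focal_site_index: int


def _forward_sweep_phase(
    alleles: np.ndarray,
    focal_col: int,
    panel_counts: np.ndarray,
    positions: np.ndarray,
    sequence_length: float,
    recombination_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conditioned forward copying phase on the swept population's panel.

    The derived class reproduces by Wright-Fisher multinomial sampling
    (keeping the genuine founder-amplification that creates long shared
    haplotypes); the ancestral class reproduces by a minimal-drift
    permutation so that panel-scale resampling does not add artificial
    drift at unlinked sites. Recombination places a single crossover per
    recombinant child, keeping the focal-site side from the class parent.
    """
    H = alleles
    M, S = H.shape
    p_rec = 1.0 - np.exp(-recombination_rate * sequence_length)
    for g in range(1, len(panel_counts)):
        k_new = int(panel_counts[g])
        der = np.flatnonzero(H[:, focal_col] == 1)
        anc = np.flatnonzero(H[:, focal_col] != 1)
        if der.size == 0:  # trajectory guarantees k>=1; guard anyway
            der = np.array([rng.integers(M)])
        d_parents = rng.choice(der, size=k_new, replace=True)
        n_anc = M - k_new
        if anc.size >= n_anc:
            a_parents = rng.permutation(anc)[:n_anc]
        else:
            extra = rng.choice(anc, size=n_anc - anc.size, replace=True)
            a_parents = np.concatenate([anc, extra])
        parents = np.concatenate([d_parents, a_parents])
        newH = H[parents]
        rec = np.flatnonzero(rng.random(M) < p_rec)
        if rec.size:
            bp = rng.random(rec.size) * sequence_length
            cuts = np.searchsorted(positions - 1, bp)
            partners = rng.integers(0, M, size=rec.size)
            for child, cut, partner in zip(rec, cuts, partners):
                if cut <= focal_col:
                    newH[child, :cut] = H[partner, :cut]
                else:
                    newH[child, cut:] = H[partner, cut:]
        H = newH
    return H


def simulate_sweep(
    model: DemographicModel,
    scenario: SweepScenario,
    samples: dict[str, int] | None = None,
    sequence_length: float = 1_000_000.0,
    seed: int | None = None,
    chromosome: str = "1",
) -> tuple[HaplotypePanel, SweepRealization]:
    """Panel with a selective sweep at the central locus of one population.

    A neutral msprime panel (with an enlarged haplotype panel for the swept
    population) supplies starting variation; the focal allele is inserted
    and driven through the conditioned frequency trajectory by the forward
    copying phase; the requested numbers of sample haplotypes are then
    drawn. Returns the panel and the realized sweep bookkeeping.
    """
    samples = dict(samples or {TARGET: 27, COMPARISON: 62})
    if scenario.population not in samples:
        raise KeyError(scenario.population)
    rng = np.random.default_rng(seed)
    traj = sweep_frequency_trajectory(model, scenario, rng)

    M = max(scenario.panel_size, 2 * samples[scenario.population])
    sim_samples = dict(samples)
    sim_samples[scenario.population] = (M + 1) // 2
    ts = _sim(model.to_msprime(), sim_samples, sequence_length, model, rng)
    panel, _ = _panel_from_ts(ts, list(sim_samples), chromosome)

    hap_pops = panel.haplotype_populations()
    swept_rows = np.flatnonzero(hap_pops == scenario.population)[:M]
    other_rows = np.flatnonzero(hap_pops != scenario.population)

    pos_f = int(scenario.position if scenario.position is not None else sequence_length // 2)
    col = int(np.searchsorted(panel.positions, pos_f))
    if col < panel.n_sites and panel.positions[col] == pos_f:
        pos_f += 1  # avoid duplicating an existing site position
        col = int(np.searchsorted(panel.positions, pos_f))

    positions = np.insert(panel.positions, col, pos_f)
    alleles = np.insert(panel.alleles, col, 0, axis=1)

    # seed the focal allele: swept-population carriers at the trajectory's
    # start frequency; for standing variation the unswept population starts
    # at the same pre-selection frequency (shared standing variant).
    x0 = float(traj[0])
    k0 = max(1, int(round(x0 * M)))
    carriers = rng.choice(swept_rows, size=min(k0, M), replace=False)
    alleles[carriers, col] = 1
    if not scenario.de_novo and scenario.onset_generations_ago > 0 and x0 > 2.0 / M:
        for row in other_rows:
            if rng.random() < x0:
                alleles[row, col] = 1

    k_panel = np.maximum(1, np.round(traj * M).astype(np.int64))
    k_panel[0] = carriers.size
    swept = _forward_sweep_phase(
        np.ascontiguousarray(alleles[swept_rows]),
        col,
        k_panel,
        positions,
        sequence_length,
        model.recombination_rate,
        rng,
    )
    alleles[swept_rows] = swept

    keep_swept = rng.choice(swept_rows, size=2 * samples[scenario.population], replace=False)
    keep = np.sort(np.concatenate([keep_swept, other_rows]))
    out_alleles = alleles[keep]
    # drop sites rendered monomorphic-ancestral by the sweep? keep them:
    # downstream statistics flag monomorphic sites themselves.
    hap_inds = panel.haplotype_individuals[keep]
    out = HaplotypePanel(
        chromosome=chromosome,
        positions=positions,
        alleles=out_alleles,
        haplotype_individuals=hap_inds,
        individual_populations=dict(panel.individual_populations),
    )
    focal_rows = out.population_haplotypes(scenario.population)
    realized = float((out.alleles[focal_rows, col] == 1).mean())
    info = SweepRealization(
        position=pos_f,
        realized_frequency=realized,
        start_frequency=x0,
        trajectory=traj,
        focal_site_index=col,
    )
    return out, info


# ---------------------------------------------------------------------------
# Archaic admixture
# ---------------------------------------------------------------------------


def _archaic_demography(
    model: DemographicModel, scenario: ArchaicScenario
) -> tuple[msprime.Demography, float]:
    scenario.validate(model)
    g = model.generation_time
    d = model.to_msprime()
    d.add_population(name="DEN", initial_size=scenario.archaic_size)
    d.add_population(name="DENI", initial_size=scenario.archaic_size)
    d.add_population(name="NEA", initial_size=scenario.archaic_size)
    d.add_population(name="ARCH", initial_size=scenario.archaic_size)
    d.add_population(name="ROOT", initial_size=model.nA1)
    for p in scenario.pulses:
        if p.fraction > 0:
            d.add_mass_migration(
                time=p.time_years / g, source=p.destination, dest=p.source,
                proportion=p.fraction,
            )
    census_time = max(p.time_years for p in scenario.pulses) / g + 2.0
    d.add_census(time=census_time)
    d.add_population_split(
        time=scenario.sampled_vs_introgressor_split_years / g,
        derived=["DENI"], ancestral="DEN",
    )
    d.add_population_split(
        time=scenario.denisovan_neanderthal_split_years / g,
        derived=["DEN", "NEA"], ancestral="ARCH",
    )
    d.add_population_split(
        time=scenario.archaic_split_years / g,
        derived=["ANC", "ARCH"], ancestral="ROOT",
    )
    d.sort_events()
    return d, census_time


def _census_tracts(
    ts: tskit.TreeSequence,
    census_time: float,
    sample_nodes: np.ndarray,
    sample_labels: np.ndarray,
    archaic_pops: dict[int, str],
) -> pd.DataFrame:
    """Per-sample intervals whose census-time ancestor sits on an archaic
    introgressing branch (true introgressed tracts, by construction)."""
    node_time = ts.tables.nodes.time
    node_pop = ts.tables.nodes.population
    rows: list[dict] = []
    open_tract: dict[int, tuple[float, str]] = {}
    for tree in ts.trees():
        left, right = tree.interval
        for s, label in zip(sample_nodes, sample_labels):
            u = s
            while u != tskit.NULL and node_time[u] < census_time:
                u = tree.parent(u)
            src = None
            if u != tskit.NULL and node_time[u] == census_time:
                src = archaic_pops.get(int(node_pop[u]))
            cur = open_tract.get(s)
            if src is not None:
                if cur is None:
                    open_tract[s] = (left, src)
                elif cur[1] != src:
                    rows.append({"haplotype": label, "left": cur[0], "right": left, "source": cur[1]})
                    open_tract[s] = (left, src)
            elif cur is not None:
                rows.append({"haplotype": label, "left": cur[0], "right": left, "source": cur[1]})
                del open_tract[s]
    L = ts.sequence_length
    for s, label in zip(sample_nodes, sample_labels):
        cur = open_tract.get(s)
        if cur is not None:
            rows.append({"haplotype": label, "left": cur[0], "right": L, "source": cur[1]})
    return pd.DataFrame(rows, columns=["haplotype", "left", "right", "source"])


def simulate_archaic(
    model: DemographicModel,
    scenario: ArchaicScenario | None = None,
    samples: dict[str, int] | None = None,
    sequence_length: float = 1_000_000.0,
    seed: int | None = None,
    chromosome: str = "1",
    track_tracts: bool = True,
) -> tuple[HaplotypePanel, SiteFrequencyTable, pd.DataFrame]:
    """Panel plus archaic genotype tracks and true introgressed tracts.

    One Denisovan and one Neanderthal diploid are sampled as archaic
    tracks; the outgroup track is the ancestral allele (known by
    construction). Returns ``(panel, site_frequency_table, tracts)`` where
    the frequency table carries the modern populations and the "DEN"/"NEA"
    archaic tracks.
    """
    scenario = scenario or ArchaicScenario()
    samples = dict(samples or {TARGET: 27, COMPARISON: 62})
    rng = np.random.default_rng(seed)
    demog, census_time = _archaic_demography(model, scenario)
    sim_samples = dict(samples)
    sim_samples["DEN"] = 1
    sim_samples["NEA"] = 1
    ts = _sim(demog, sim_samples, sequence_length, model, rng)

    full_panel, _ = _panel_from_ts(ts, list(sim_samples), chromosome)
    pops = full_panel.haplotype_populations()
    modern_rows = np.flatnonzero(np.isin(pops, list(samples)))
    den_rows = np.flatnonzero(pops == "DEN")
    nea_rows = np.flatnonzero(pops == "NEA")
    panel = full_panel.subset(haplotypes=modern_rows)

    def _track(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sub = full_panel.alleles[rows]
        return (sub == 1).sum(axis=0).astype(np.int64), (sub != -1).sum(axis=0).astype(np.int64)

    sft = site_frequency_table(
        panel,
        populations=list(samples),
        archaic={"DEN": _track(den_rows), "NEA": _track(nea_rows)},
    )

    if track_tracts:
        pop_ids = {p.id: p.metadata.get("name") for p in ts.populations()}
        archaic_ids = {pid: name for pid, name in pop_ids.items() if name in ("DENI", "NEA")}
        sample_nodes = np.array(ts.samples())
        node_pop_names = np.array([pop_ids[ts.node(u).population] for u in sample_nodes])
        modern = np.isin(node_pop_names, list(samples))
        labels = np.array([
            f"{pop_ids[ts.node(u).population]}_{ts.node(u).individual}_{u}" for u in sample_nodes
        ])
        tracts = _census_tracts(
            ts, census_time, sample_nodes[modern], labels[modern], archaic_ids
        )
        n_modern = int(modern.sum())
        tracts.attrs["n_modern_haplotypes"] = n_modern
        tracts.attrs["sequence_length"] = float(ts.sequence_length)
    else:
        tracts = pd.DataFrame(columns=["haplotype", "left", "right", "source"])
    return panel, sft, tracts
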