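"""Forward simulation of partially selfing populations and experiment tables.

The generator mirrors the study system: populations of self-fertilising
hermaphrodites with a tunable outcrossing rate, several divergent lineages
founded from one ancestral population, isogenic strains established by
repeated single-worm selfing, recent between-lineage admixture producing
mosaic haplotypes, and male/hermaphrodite offspring-count experiments with a
climate-group x temperature interaction.

The simulation is an explicit forward Wright-Fisher model rather than a
coalescent: each generation every offspring is produced by selfing with
probability ``selfing_rate``, otherwise by two distinct uniformly drawn
parents; gametes carry Poisson-distributed crossovers and infinite-sites
mutations at unique integer positions. Transparency of the mating mechanics
(partial selfing, inbred-line sampling, recent crosses) is preferred over
speed, which is adequate at the scales used here (hundreds of individuals,
megabase sequences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from andromix.genotypes_io import CLIMATE_GROUPS, HaplotypeMatrix


class MonomorphicSampleError(RuntimeError):
    """No polymorphic sites among the sampled strains."""


@dataclass
class SimulationConfig:
    """Parameters of the partial-selfing Wright-Fisher simulation.

    Defaults give a desk-scale population: 200 diploid hermaphrodites on a
    1 Mb sequence with per-bp mutation and crossover rates of 1e-7 and a
    burn-in of 10N generations.
    """

    n_individuals: int = 200
    selfing_rate: float = 0.9
    mutation_rate: float = 1e-7
    recomb_rate: float = 1e-7
    seq_length: int = 1_000_000
    n_generations: int | None = None  # default 10 * n_individuals
    n_sampled_strains: int = 40
    inbreed_generations: int = 10
    n_contigs: int = 1  # independent windows emulating separate chromosomes
    seed: int = 0

    def __post_init__(self):
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.mutation_rate < 0 or self.recomb_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.seq_length < 2:
            raise ValueError("seq_length must be >= 2")
        if self.n_sampled_strains > self.n_individuals:
            raise ValueError("n_sampled_strains must be <= n_individuals")
        if self.n_generations is None:
            self.n_generations = 10 * self.n_individuals


@dataclass
class AdmixtureDesign:
    """An F1 cross between two source pools followed by selfing generations.

    ``source_a``/``source_b`` are haplotype matrices over the same sites
    (e.g. two lineages of one simulated panel). Each admixed strain starts as
    an F1 of one random haplotype from each source and then selfs
    ``generations_since_cross`` times with recombination, yielding a block
    mosaic. ``label`` is the lineage the admixed strains are filed under
    (default: the majority lineage of ``source_b``, emulating an admixed
    group nested inside one lineage).
    """

    source_a: HaplotypeMatrix
    source_b: HaplotypeMatrix
    n_admixed: int = 4
    generations_since_cross: int = 5
    seed: int = 0
    recomb_rate: float | None = None  # default: source provenance
    label: str | None = None

    def __post_init__(self):
        if self.generations_since_cross < 1:
            raise ValueError("generations_since_cross must be >= 1")
        if self.n_admixed < 1:
            raise ValueError("n_admixed must be >= 1")


@dataclass
class MaleCountDesign:
    """Design of the male-production plate experiment generator.

    Each strain x temperature x replicate yields a Poisson total brood split
    binomially into males and hermaphrodites, with
    logit(p_male) = baseline + interaction(climate group, temperature)
    + strain random effect. Hermaphrodite counts are rounded to the nearest
    50 (minimum 50) as on the real plates; male counts are exact.
    """

    localities: dict = field(default_factory=lambda: dict(CLIMATE_GROUPS))
    treatments: tuple = (15, 20, 25)
    n_strains_per_locality: int = 6
    n_replicates: int = 3
    baseline_male_logit: float = -4.0
    interaction_effects: dict = field(default_factory=dict)
    strain_sd: float = 0.5
    brood_size_mean: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not self.localities:
            raise ValueError("localities must be non-empty")
        if not self.treatments:
            raise ValueError("treatments must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.brood_size_mean <= 0:
            raise ValueError("brood_size_mean must be > 0")


def antagonistic_interaction(scale: float = 1.0) -> dict:
    """Climate x temperature logit shifts with the observed sign pattern:
    cold-climate strains make more males when warm, mid-warm-climate strains
    when cold; mid-cold mildly mirrors mid-warm; warm flat."""
    return {
        ("cold", 15): -scale, ("cold", 20): 0.0, ("cold", 25): +scale,
        ("mid-cold", 15): +scale / 2, ("mid-cold", 20): 0.0,
        ("mid-cold", 25): -scale / 2,
        ("mid-warm", 15): +scale, ("mid-warm", 20): 0.0,
        ("mid-warm", 25): -scale,
        ("warm", 15): 0.0, ("warm", 20): 0.0, ("warm", 25): 0.0,
    }


# ---------------------------------------------------------------------------
# Wright-Fisher engine. A haplotype is a sorted int64 array of the positions
# of the derived mutations it carries (infinite sites: every position unique
# population-wide, enforced by resampling collisions). Arrays are treated as
# immutable so unchanged gametes are passed by reference.
# ---------------------------------------------------------------------------

def _make_gamete(ind, n_x, n_m, which, length, rng, used):
    h0, h1 = ind
    if n_x == 0:
        gamete = h0 if which == 0 else h1
    else:
        bounds = np.empty(n_x + 2)
        bounds[0] = 0.0
        bounds[1:-1] = np.sort(rng.uniform(0.0, length, n_x))
        bounds[-1] = length + 1.0
        parts = []
        pair = (h0, h1)
        active = which
        for k in range(n_x + 1):
            hap = pair[active]
            lo, hi = np.searchsorted(hap, (bounds[k], bounds[k + 1]))
            parts.append(hap[lo:hi])
            active ^= 1
        gamete = np.concatenate(parts)
    if n_m:
        fresh = np.empty(n_m, dtype=np.int64)
        for i in range(n_m):
            pos = int(rng.integers(1, length + 1))
            while pos in used:
                pos = int(rng.integers(1, length + 1))
            used.add(pos)
            fresh[i] = pos
        gamete = np.sort(np.concatenate([gamete, fresh]))
    return gamete


def _evolve(pop, n_generations, cfg: SimulationConfig, rng, used):
    n = len(pop)
    mean_x = cfg.recomb_rate * cfg.seq_length
    mean_m = cfg.mutation_rate * cfg.seq_length
    for _ in range(n_generations):
        selfs = rng.random(n) < cfg.selfing_rate
        pa = rng.integers(0, n, n)
        pb = rng.integers(0, n, n)
        clash = (~selfs) & (pb == pa)
        while np.any(clash):
            pb[clash] = rng.integers(0, n, int(clash.sum()))
            clash = (~selfs) & (pb == pa)
        pb[selfs] = pa[selfs]
        n_x = rng.poisson(mean_x, 2 * n)
        n_m = rng.poisson(mean_m, 2 * n)
        which = rng.integers(0, 2, 2 * n)
        nxt = []
        for i in range(n):
            ga = _make_gamete(pop[pa[i]], n_x[2 * i], n_m[2 * i],
                              which[2 * i], cfg.seq_length, rng, used)
            gb = _make_gamete(pop[pb[i]], n_x[2 * i + 1], n_m[2 * i + 1],
                              which[2 * i + 1], cfg.seq_length, rng, used)
            nxt.append((ga, gb))
        pop = nxt
    return pop


def _self_line(ind, n_generations, cfg: SimulationConfig, rng, used):
    """Repeated single-individual selfing (isogenic-line establishment)."""
    mean_x = cfg.recomb_rate * cfg.seq_length
    mean_m = cfg.mutation_rate * cfg.seq_length
    for _ in range(n_generations):
        ind = tuple(
            _make_gamete(ind, rng.poisson(mean_x), rng.poisson(mean_m),
                         int(rng.integers(0, 2)), cfg.seq_length, rng, used)
            for _ in range(2)
        )
    return ind


def _population_het(pop):
    """(mean observed het, mean Hardy-Weinberg het, segregating-site count)
    over segregating sites of a diploid population."""
    n = len(pop)
    everything = np.concatenate([np.concatenate(ind) for ind in pop])
    pos, counts = np.unique(everything, return_counts=True)
    seg = counts < 2 * n
    pos, counts = pos[seg], counts[seg]
    if pos.size == 0:
        return 0.0, 0.0, 0
    freq = counts / (2 * n)
    h_exp = 2 * freq * (1 - freq)
    het_positions = np.concatenate([np.setxor1d(h0, h1) for h0, h1 in pop])
    hpos, hcounts = np.unique(het_positions, return_counts=True)
    idx = np.searchsorted(pos, hpos)
    inside = (idx < pos.size) & (pos[np.minimum(idx, pos.size - 1)] == hpos)
    h_obs = np.zeros(pos.size)
    h_obs[idx[inside]] = hcounts[inside] / n
    return float(h_obs.mean()), float(h_exp.mean()), int(pos.size)


def _window_sites(haplotypes):
    """Polymorphic (positions, 0/1 matrix) for one window's emitted gametes."""
    nonempty = [h for h in haplotypes if h.size]
    if not nonempty:
        return np.empty(0, dtype=np.int64), \
            np.zeros((len(haplotypes), 0), dtype=np.int8)
    pos = np.unique(np.concatenate(nonempty))
    alleles = np.zeros((len(haplotypes), pos.size), dtype=np.int8)
    for i, hap in enumerate(haplotypes):
        alleles[np.full(hap.size, i), np.searchsorted(pos, hap)] = 1
    carriers = alleles.sum(axis=0)
    poly = (carriers >= 1) & (carriers < len(haplotypes))
    return pos[poly], alleles[:, poly]


def _assemble(windows, strains, lineages, cfg, meta):
    """Stack per-window (positions, alleles) into one matrix with contig ids
    c1..ck; error if nothing is polymorphic anywhere."""
    contigs, positions, blocks = [], [], []
    for w, (pos, alleles) in enumerate(windows):
        if pos.size:
            contigs.append(np.full(pos.size, f"c{w + 1}", dtype=object))
            positions.append(pos)
            blocks.append(alleles)
    if not positions:
        raise MonomorphicSampleError(
            "monomorphic sample: no polymorphic sites among the sampled "
            "strains; increase seq_length or mutation_rate"
        )
    matrix = HaplotypeMatrix(
        strains=strains,
        lineages=lineages,
        contigs=np.concatenate(contigs),
        positions=np.concatenate(positions),
        alleles=np.hstack(blocks),
        meta=meta,
    )
    matrix.meta.setdefault("config", asdict(cfg))
    return matrix


def simulate_selfing_population(config: SimulationConfig) -> HaplotypeMatrix:
    """Simulate a partially selfing population and sample isogenic strains.

    ``n_contigs`` independent windows (stand-ins for separate chromosomes)
    are simulated with identical parameters. In each, after the burn-in,
    ``n_sampled_strains`` individuals are drawn without replacement, each is
    selfed ``inbreed_generations`` times (isogenic-line establishment) and
    one gamete per line is emitted as the strain haplotype. Sites are
    restricted to those polymorphic among the sample. Provenance in ``meta``
    records the true selfing rate, the realized population inbreeding
    coefficient F = 1 - H_obs/H_exp, and the mean residual heterozygosity of
    the inbred lines relative to the population's Hardy-Weinberg
    expectation.
    """
    spawn = np.random.SeedSequence(config.seed).spawn(config.n_contigs)
    n_lines = config.n_sampled_strains
    windows, f_vals, h_obs_all, h_exp_all, seg_all, inbred_all = [], [], [], [], [], []
    mean_x = config.recomb_rate * config.seq_length
    mean_m = config.mutation_rate * config.seq_length
    empty = np.empty(0, dtype=np.int64)
    for sub in spawn:
        rng = np.random.default_rng(sub)
        used: set = set()
        pop = [(empty, empty)] * config.n_individuals
        pop = _evolve(pop, config.n_generations, config, rng, used)
        h_obs, h_exp, n_seg = _population_het(pop)
        if h_exp > 0:
            f_vals.append(1.0 - h_obs / h_exp)
        h_obs_all.append(h_obs)
        h_exp_all.append(h_exp)
        seg_all.append(n_seg)
        chosen = rng.choice(config.n_individuals, n_lines, replace=False)
        haplotypes = []
        for idx in chosen:
            line = _self_line(pop[idx], config.inbreed_generations, config,
                              rng, used)
            if n_seg:
                inbred_all.append(np.setxor1d(*line).size / n_seg)
            haplotypes.append(
                _make_gamete(line, rng.poisson(mean_x), rng.poisson(mean_m),
                             int(rng.integers(0, 2)), config.seq_length,
                             rng, used)
            )
        windows.append(_window_sites(haplotypes))
    meta = {
        "true_selfing_rate": config.selfing_rate,
        "inbreeding_coefficient": float(np.mean(f_vals)) if f_vals
        else float("nan"),
        "pop_h_obs_mean": float(np.mean(h_obs_all)),
        "pop_h_exp_mean": float(np.mean(h_exp_all)),
        "pop_segregating_sites": int(np.sum(seg_all)),
        "inbred_het_mean": float(np.mean(inbred_all)) if inbred_all else 0.0,
    }
    strains = [f"S{i:03d}" for i in range(n_lines)]
    return _assemble(windows, strains, ["A"] * n_lines, config, meta)


def simulate_divergent_lineages(config: SimulationConfig, n_lineages: int = 2,
                                split_generations: int = 2000) -> HaplotypeMatrix:
    """One ancestral burn-in split into lineages evolved independently.

    Each lineage receives ``config.n_sampled_strains`` strains labelled
    A, B, C, ... in one combined matrix (sites polymorphic across the whole
    sample); with ``n_contigs > 1`` the split is replayed on every window.
    """
    if n_lineages < 2:
        raise ValueError("n_lineages must be >= 2")
    n_lines = config.n_sampled_strains
    strains = [f"{chr(ord('A') + li)}{k:03d}"
               for li in range(n_lineages) for k in range(n_lines)]
    lineages = [s[0] for s in strains]
    mean_x = config.recomb_rate * config.seq_length
    mean_m = config.mutation_rate * config.seq_length
    empty = np.empty(0, dtype=np.int64)
    windows = []
    for sub in np.random.SeedSequence(config.seed).spawn(config.n_contigs):
        seeds = sub.spawn(n_lineages + 1)
        rng = np.random.default_rng(seeds[0])
        used: set = set()
        pop = [(empty, empty)] * config.n_individuals
        pop = _evolve(pop, config.n_generations, config, rng, used)
        haplotypes = []
        for li in range(n_lineages):
            lrng = np.random.default_rng(seeds[li + 1])
            lineage_pop = _evolve(list(pop), split_generations, config,
                                  lrng, used)
            chosen = lrng.choice(config.n_individuals, n_lines, replace=False)
            for idx in chosen:
                line = _self_line(lineage_pop[idx], config.inbreed_generations,
                                  config, lrng, used)
                haplotypes.append(
                    _make_gamete(line, lrng.poisson(mean_x),
                                 lrng.poisson(mean_m),
                                 int(lrng.integers(0, 2)), config.seq_length,
                                 lrng, used)
                )
        windows.append(_window_sites(haplotypes))
    meta = {"split_generations": split_generations,
            "true_selfing_rate": config.selfing_rate}
    return _assemble(windows, strains, lineages, config, meta)


def simulate_admixed_mosaic(design: AdmixtureDesign) -> HaplotypeMatrix:
    """Produce mosaic haplotypes from recent between-lineage crosses.

    Each admixed strain is founded as an F1 of one haplotype from each
    source, then selfed ``generations_since_cross`` times with Poisson
    crossovers (de-novo mutation over these few generations is negligible
    against standing divergence and is omitted). The per-site true ancestry
    (0 = source_a, 1 = source_b) of every emitted haplotype is stored in
    ``meta["ancestry"]``.
    """
    a, b = design.source_a, design.source_b
    if not (np.array_equal(a.positions, b.positions)
            and np.array_equal(a.contigs, b.contigs)):
        raise ValueError("sources must share an identical site grid")
    if np.array_equal(a.alleles, b.alleles):
        warnings.warn("sources not divergent: ancestry is unidentifiable",
                      stacklevel=2)
    rng = np.random.default_rng(design.seed)
    cfg = a.meta.get("config", {})
    length = int(cfg.get("seq_length", int(a.positions.max()) + 1))
    recomb_rate = (design.recomb_rate if design.recomb_rate is not None
                   else float(cfg.get("recomb_rate", 0.0)))
    mean_x = recomb_rate * length
    contig_cols = [(np.flatnonzero(a.contigs == c),
                    a.positions[a.contigs == c].astype(float))
                   for c in a.contig_ids()]

    def meiosis(diploid):
        # contigs assort independently; Poisson crossovers within each
        (al0, an0), (al1, an1) = diploid
        out_al = np.empty_like(al0)
        out_an = np.empty_like(an0)
        for cols, pos in contig_cols:
            n_x = rng.poisson(mean_x)
            if n_x == 0:
                take0 = bool(rng.integers(0, 2))
                src_al, src_an = (al0, an0) if take0 else (al1, an1)
                out_al[cols] = src_al[cols]
                out_an[cols] = src_an[cols]
            else:
                breaks = np.sort(rng.uniform(0.0, length, n_x))
                seg = np.searchsorted(breaks, pos)
                take0 = (seg + int(rng.integers(0, 2))) % 2 == 0
                out_al[cols] = np.where(take0, al0[cols], al1[cols])
                out_an[cols] = np.where(take0, an0[cols], an1[cols])
        return out_al, out_an

    n_sites = a.n_sites
    alleles = np.empty((design.n_admixed, n_sites), dtype=np.int8)
    ancestry = np.empty((design.n_admixed, n_sites), dtype=np.int8)
    for i in range(design.n_admixed):
        ha = a.alleles[rng.integers(0, a.n_strains)]
        hb = b.alleles[rng.integers(0, b.n_strains)]
        diploid = ((ha.copy(), np.zeros(n_sites, dtype=np.int8)),
                   (hb.copy(), np.ones(n_sites, dtype=np.int8)))
        for _ in range(design.generations_since_cross):
            diploid = (meiosis(diploid), meiosis(diploid))
        alleles[i], ancestry[i] = diploid[int(rng.integers(0, 2))]

    label = design.label
    if label is None:
        labels_b = pd.Series(b.lineages)
        label = labels_b.mode().iloc[0] if len(labels_b) else "B"
    strains = [f"X{i:03d}" for i in range(design.n_admixed)]
    return HaplotypeMatrix(
        strains=strains,
        lineages=[label] * design.n_admixed,
        contigs=a.contigs.copy(),
        positions=a.positions.copy(),
        alleles=alleles,
        meta={"ancestry": ancestry, "true_admixed": True,
              "generations_since_cross": design.generations_since_cross},
    )


def concat_strains(matrices) -> HaplotypeMatrix:
    """Stack matrices sharing one site grid into a single panel."""
    first = matrices[0]
    for m in matrices[1:]:
        if not (np.array_equal(m.positions, first.positions)
                and np.array_equal(m.contigs, first.contigs)):
            raise ValueError("matrices must share an identical site grid")
    return HaplotypeMatrix(
        strains=sum((list(m.strains) for m in matrices), []),
        lineages=sum((list(m.lineages) for m in matrices), []),
        contigs=first.contigs.copy(),
        positions=first.positions.copy(),
        alleles=np.vstack([m.alleles for m in matrices]),
        meta={"combined_from": len(matrices)},
    )


def simulate_male_counts(design: MaleCountDesign) -> pd.DataFrame:
    """Simulate the plate experiment: male/hermaphrodite counts per
    strain x temperature x replicate.

    Returns a table with columns strain, locality, climate_group,
    temperature_C, replicate, males, hermaphrodites. Male counts are exact;
    hermaphrodite counts are rounded to the nearest 50 (minimum 50),
    mimicking clumped-plate counting.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for locality, group in design.localities.items():
        for s in range(design.n_strains_per_locality):
            strain = f"{locality}{s:02d}"
            strain_effect = rng.normal(0.0, design.strain_sd)
            for temp in design.treatments:
                shift = design.interaction_effects.get((group, temp), 0.0)
                p_male = expit(design.baseline_male_logit + shift + strain_effect)
                for rep in range(1, design.n_replicates + 1):
                    brood = rng.poisson(design.brood_size_mean)
                    males = int(rng.binomial(brood, p_male)) if brood else 0
                    herm = max(50, int(round((brood - males) / 50.0)) * 50)
                    rows.append((strain, locality, group, temp, rep,
                                 males, herm))
    return pd.DataFrame(rows, columns=[
        "strain", "locality", "climate_group", "temperature_C", "replicate",
        "males", "hermaphrodites",
    ])
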