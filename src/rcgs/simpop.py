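"""Forward simulation of a wheat-like breeding population.

Emulates the structure of a rapid-cycle recurrent genomic selection
training set: 16 inbred founders crossed into 14 bi-parental families,
advanced by selfing to F4 lines, with an additive (optionally
additive-by-additive) yield-like trait and per-family heritability
targets spanning the very wide range observed in real bi-parental
families (~0.01 to ~0.73).

The genetic model is deliberately simple: a Haldane (no-interference)
crossover process with Poisson crossover counts per chromosome, unlinked
chromosomes of configurable map length, and founder allele frequencies
drawn Uniform(0.1, 0.9) so downstream MAF filtering has non-trivial
action.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .genotypes import MarkerMatrix
from .kinship import Pedigree

__all__ = [
    "FounderSet",
    "SimIndividual",
    "TraitArchitecture",
    "TrainingPopConfig",
    "make_founders",
    "meiosis",
    "cross",
    "self_advance",
    "true_breeding_values",
    "assign_phenotypes",
    "make_training_population",
]

#: Table-style default family sizes (sum 1609): eleven families of 94-95
#: lines and three of 186-190.
DEFAULT_FAMILY_SIZES = (94, 190, 190, 95, 95, 95, 95, 95, 94, 95, 95, 95, 95, 186)

#: Default per-family line-mean heritability targets, spanning the
#: low-to-high range seen across real bi-parental families.
DEFAULT_FAMILY_H2 = (0.39, 0.44, 0.56, 0.73, 0.07, 0.55, 0.44, 0.01,
                     0.04, 0.32, 0.48, 0.55, 0.44, 0.28)


@dataclasses.dataclass
class FounderSet:
    """Phased founder haplotypes plus the shared genetic map."""

    haplotypes: np.ndarray  # (n_founders, 2, n_markers) in {0,1}
    map_positions: np.ndarray  # Morgans within chromosome, non-decreasing
    chromosomes: np.ndarray  # chromosome index per marker
    chrom_lengths: np.ndarray  # Morgans per chromosome
    ids: list[str]

    def __post_init__(self):
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_founders, 2, n_markers)")
        if self.n_markers == 0:
            raise ValueError("marker count must be > 0")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        for c in np.unique(self.chromosomes):
            p = self.map_positions[self.chromosomes == c]
            if np.any(np.diff(p) < 0):
                raise ValueError("map positions must be non-decreasing within chromosome")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]


@dataclasses.dataclass
class SimIndividual:
    """One simulated plant/line: a phased haplotype pair plus bookkeeping."""

    id: str
    haplotypes: np.ndarray  # (2, n_markers) in {0,1}
    parent1: str | None = None
    parent2: str | None = None
    generation: str = "F1"
    family: str | None = None
    true_breeding_value: float | None = None
    selfing_generations: int = 0  # since the recorded parents' cross

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)

    @property
    def heterozygosity(self) -> float:
        return float((self.haplotypes[0] != self.haplotypes[1]).mean())


@dataclasses.dataclass
class TraitArchitecture:
    """Additive (+ optional additive-x-additive) genetic architecture.

    ``additive_effects`` has one entry per marker (zeros at non-QTL).
    ``epistatic_pairs`` holds (i, j, effect) triples acting on centered
    dosages.  ``env_variance`` is the per-observation error variance in
    squared trait units; when ``family_h2_targets`` is supplied it is
    recalibrated per family from the realized within-family genetic
    variance.
    """

    additive_effects: np.ndarray
    intercept: float = 0.0
    epistatic_pairs: list[tuple[int, int, float]] = dataclasses.field(default_factory=list)
    env_variance: float = 1.0
    family_h2_targets: dict[str, float] | None = None

    def __post_init__(self):
        self.additive_effects = np.asarray(self.additive_effects, dtype=float)
        if not np.isfinite(self.additive_effects).all():
            raise ValueError("additive effects must be finite")
        if self.env_variance < 0:
            raise ValueError("env_variance must be >= 0")


@dataclasses.dataclass
class TrainingPopConfig:
    """Shape of the simulated training population (defaults emulate the
    16-founder, 14-family, 1,609-line study design)."""

    n_founders: int = 16
    n_markers: int = 7000
    n_chromosomes: int = 21
    chrom_length_morgans: float = 1.0
    family_sizes: tuple = DEFAULT_FAMILY_SIZES
    family_h2_targets: tuple = DEFAULT_FAMILY_H2
    selfing_generations: int = 2  # F2 -> F4
    bulk_size: int = 3  # "selected bulk" candidates per advancement step
    n_qtl: int = 300
    intercept: float = 6.7  # ton/ha scale
    genetic_sd: float = 0.45  # SD of founder-population breeding values
    n_reps: int = 2

    def __post_init__(self):
        if len(self.family_sizes) != len(self.family_h2_targets):
            raise ValueError("family_sizes and family_h2_targets lengths differ")


# ---------------------------------------------------------------------------
# Founders and meiosis


def make_founders(
    n_founders: int,
    n_markers: int,
    n_chromosomes: int,
    seed: int,
    freq_range: tuple[float, float] = (0.1, 0.9),
    chrom_length_morgans: float = 1.0,
    inbred: bool = True,
) -> FounderSet:
    """Draw a founder panel with per-marker allele frequencies from
    Uniform(freq_range).  ``inbred=True`` (the default, matching elite
    breeding parents) makes each founder fully homozygous."""
    if min(n_founders, n_markers, n_chromosomes) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=n_markers)
    if inbred:
        alleles = (rng.random((n_founders, n_markers)) < freqs).astype(np.int8)
        haps = np.repeat(alleles[:, None, :], 2, axis=1)
    else:
        haps = (rng.random((n_founders, 2, n_markers)) < freqs).astype(np.int8)
    per_chrom = np.array_split(np.arange(n_markers), n_chromosomes)
    chroms = np.empty(n_markers, dtype=int)
    positions = np.empty(n_markers)
    for c, idx in enumerate(per_chrom):
        chroms[idx] = c
        positions[idx] = np.sort(rng.uniform(0, chrom_length_morgans, size=len(idx)))
    return FounderSet(
        haplotypes=haps,
        map_positions=positions,
        chromosomes=chroms,
        chrom_lengths=np.full(n_chromosomes, chrom_length_morgans),
        ids=[f"P{k+1}" for k in range(n_founders)],
    )


def meiosis(parent: SimIndividual, founders: FounderSet, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete under the Haldane model: crossover count per
    chromosome ~ Poisson(map length in Morgans), positions uniform, no
    interference.  E[gamete allele] = parent dosage / 2 marker-wise."""
    haps = parent.haplotypes
    gamete = np.empty(founders.n_markers, dtype=np.int8)
    for c, L in enumerate(founders.chrom_lengths):
        idx = founders.chromosomes == c
        pos = founders.map_positions[idx]
        n_xo = rng.poisson(L) if L > 0 else 0
        start = rng.integers(2)
        if n_xo == 0:
            phase = np.full(pos.size, start)
        else:
            xo = np.sort(rng.uniform(0, L, size=n_xo))
            phase = (start + np.searchsorted(xo, pos)) % 2
        gamete[idx] = np.where(phase == 0, haps[0, idx], haps[1, idx])
    return gamete


def cross(
    p1: SimIndividual,
    p2: SimIndividual,
    n_offspring: int,
    rng: np.random.Generator,
    founders: FounderSet,
    id_prefix: str = "X",
    generation: str = "F1",
    family: str | None = None,
) -> list[SimIndividual]:
    """Mate two individuals: each offspring receives one recombinant
    gamete from each parent; pedigree links are recorded."""
    out = []
    for k in range(n_offspring):
        haps = np.stack([meiosis(p1, founders, rng), meiosis(p2, founders, rng)])
        out.append(
            SimIndividual(
                id=f"{id_prefix}_{k+1}" if n_offspring > 1 else id_prefix,
                haplotypes=haps,
                parent1=p1.id,
                parent2=p2.id,
                generation=generation,
                family=family,
            )
        )
    return out


def self_advance(
    ind: SimIndividual,
    n_generations: int,
    rng: np.random.Generator,
    founders: FounderSet,
    bulk_policy: int = 1,
    id_suffix: str | None = None,
) -> SimIndividual:
    """Advance a line by repeated self-fertilization.

    ``bulk_policy`` k samples k selfed candidates per generation and keeps
    one at random (a non-selective stand-in for "selected bulk"
    advancement); k=1 is single-seed descent.  Expected per-marker
    heterozygosity halves each generation.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if bulk_policy < 1:
        raise ValueError("bulk_policy must be >= 1")
    current = ind
    for _ in range(n_generations):
        candidates = [
            np.stack([meiosis(current, founders, rng), meiosis(current, founders, rng)])
            for _ in range(bulk_policy)
        ]
        haps = candidates[rng.integers(bulk_policy)]
        current = SimIndividual(
            id=current.id,
            haplotypes=haps,
            parent1=current.parent1,
            parent2=current.parent2,
            generation=current.generation,
            family=current.family,
            selfing_generations=current.selfing_generations + 1,
        )
    if id_suffix:
        current.id = ind.id + id_suffix
    return current


# ---------------------------------------------------------------------------
# Phenotypes


def true_breeding_values(pop: list[SimIndividual], arch: TraitArchitecture) -> np.ndarray:
    """Genetic value of each individual: intercept + sum of additive
    effects times dosage + additive-x-additive terms on centered dosages.
    Also stored on each individual."""
    D = np.stack([ind.dosage for ind in pop]).astype(float)
    g = arch.intercept + D @ arch.additive_effects
    if arch.epistatic_pairs:
        Dc = D - 1.0
        for i, j, eff in arch.epistatic_pairs:
            g = g + eff * Dc[:, i] * Dc[:, j]
    for ind, v in zip(pop, g):
        ind.true_breeding_value = float(v)
    return g


def _calibrated_env_variance(g: np.ndarray, h2: float, r: int) -> float:
    """Per-observation error variance giving line-mean heritability h2 at
    r replicates, from the realized genetic variance of the group."""
    sigma_g = float(np.var(g))
    if h2 <= 0:
        raise ValueError("h2 target must be > 0")
    if h2 >= 1:
        return 0.0
    if sigma_g == 0:
        return 0.0
    return r * sigma_g * (1.0 - h2) / h2


def assign_phenotypes(
    pop: list[SimIndividual],
    arch: TraitArchitecture,
    r_reps: int,
    seed: int,
    trait: str = "GY",
    years: tuple = (1,),
) -> pd.DataFrame:
    """Simulate replicated phenotypes: value = genetic value + iid
    N(0, env_variance) noise per (rep, year) observation.

    When ``arch.family_h2_targets`` is given, the error variance is
    calibrated per family from that family's realized genetic variance so
    the line-mean heritability approximates the target.  Returns a long
    table (line, family, trait, rep, year, value).
    """
    rng = np.random.default_rng(seed)
    g = true_breeding_values(pop, arch)
    n = len(pop)
    fams = np.array([ind.family for ind in pop], dtype=object)
    env_var = np.full(n, arch.env_variance)
    if arch.family_h2_targets:
        for fam, h2 in arch.family_h2_targets.items():
            mask = fams == fam
            if mask.any():
                env_var[mask] = _calibrated_env_variance(g[mask], h2, r_reps)
    rows = []
    for year in years:
        for rep in range(1, r_reps + 1):
            noise = rng.normal(0.0, np.sqrt(env_var))
            for ind, gv, e in zip(pop, g, noise):
                rows.append((ind.id, ind.family, trait, rep, year, gv + e))
    return pd.DataFrame(rows, columns=["line", "family", "trait", "rep", "year", "value"])


# ---------------------------------------------------------------------------
# Whole training population


def _founder_pairs(n_founders: int, n_families: int, rng: np.random.Generator):
    """Distinct founder pairs for the bi-parental families, using every
    founder at least once when possible."""
    founders = list(range(n_founders))
    rng.shuffle(founders)
    pairs = [
        (founders[2 * k], founders[2 * k + 1]) for k in range(n_founders // 2)
    ]
    all_pairs = list(itertools.combinations(range(n_founders), 2))
    rng.shuffle(all_pairs)
    used = {tuple(sorted(p)) for p in pairs}
    for p in all_pairs:
        if len(pairs) >= n_families:
            break
        if tuple(sorted(p)) not in used:
            pairs.append(p)
            used.add(tuple(sorted(p)))
    if len(pairs) < n_families:
        raise ValueError("not enough distinct founder pairs for requested families")
    return pairs[:n_families]


def make_training_population(config: TrainingPopConfig, seed: int):
    """Build the full synthetic training set: founders -> 14 bi-parental
    F2 families -> selfed lines (F4 by default) with phenotypes.

    Returns (MarkerMatrix, Pedigree, phenotype DataFrame, family labels
    Series, extras dict).  ``extras`` carries the FounderSet, the
    TraitArchitecture and the SimIndividual lines for downstream
    simulation stages.
    """
    rng = np.random.default_rng(seed)
    fs = make_founders(
        config.n_founders,
        config.n_markers,
        config.n_chromosomes,
        seed=int(rng.integers(2**31)),
        chrom_length_morgans=config.chrom_length_morgans,
    )
    founders = [
        SimIndividual(id=fs.ids[k], haplotypes=fs.haplotypes[k], generation="P")
        for k in range(fs.n_founders)
    ]

    # trait architecture: n_qtl markers with normal effects, rescaled so
    # founder-population breeding-value SD hits config.genetic_sd
    qtl = rng.choice(config.n_markers, size=min(config.n_qtl, config.n_markers), replace=False)
    effects = np.zeros(config.n_markers)
    effects[qtl] = rng.normal(size=qtl.size)
    D0 = np.stack([f.dosage for f in founders]).astype(float)
    sd0 = float(np.std(D0 @ effects))
    if sd0 > 0:
        effects *= config.genetic_sd / sd0
    fam_names = [f"F{k+1}" for k in range(len(config.family_sizes))]
    arch = TraitArchitecture(
        additive_effects=effects,
        intercept=config.intercept - float(np.mean(D0 @ effects)),
        env_variance=1.0,
        family_h2_targets=dict(zip(fam_names, config.family_h2_targets)),
    )

    pairs = _founder_pairs(config.n_founders, len(config.family_sizes), rng)
    lines: list[SimIndividual] = []
    ped_tuples = [(f.id, 0, 0, 0) for f in founders]
    for fam, (ia, ib), size in zip(fam_names, pairs, config.family_sizes):
        pa, pb = founders[ia], founders[ib]
        f1 = cross(pa, pb, 1, rng, fs, id_prefix=f"{fam}_F1", family=fam)[0]
        ped_tuples.append((f1.id, pa.id, pb.id, 0))
        for k in range(size):
            # one F2 plant per line, selfed on to the target generation
            f2 = cross(f1, f1, 1, rng, fs, id_prefix=f"{fam}_L{k+1}",
                       generation="F2", family=fam)[0]
            line = f2
            if config.selfing_generations > 0:
                line = self_advance(
                    f2, config.selfing_generations, rng, fs,
                    bulk_policy=config.bulk_size,
                )
            line.generation = f"F{2 + config.selfing_generations}"
            lines.append(line)
            ped_tuples.append((line.id, f1.id, f1.id, config.selfing_generations))

    mm = MarkerMatrix(
        individual_ids=np.array([l.id for l in lines], dtype=object),
        marker_ids=np.array([f"M{j+1}" for j in range(config.n_markers)], dtype=object),
        dosages=np.stack([l.dosage for l in lines]).astype(float),
        chrom=np.array([f"chr{c+1}" for c in fs.chromosomes], dtype=object),
        pos=np.arange(1, config.n_markers + 1),
    )
    pheno = assign_phenotypes(lines, arch, r_reps=config.n_reps,
                              seed=int(rng.integers(2**31)))
    ped = Pedigree.from_tuples(ped_tuples)
    families = pd.Series([l.family for l in lines], index=[l.id for l in lines],
                         name="family")
    extras = {"founders": fs, "architecture": arch, "lines": lines,
              "founder_individuals": founders}
    return mm, ped, pheno, families, extras
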