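"""Synthetic study generator: pedigrees, genotypes, trait architectures, phenotypes.

Emulates an F2 cross between two divergent founder lines (the structure of a
Pekin x mallard resource population) at desk scale: founder haplotypes with
within-chromosome LD, gene dropping with recombination down a recorded
pedigree, marker-effect architectures matching each Bayesian-alphabet prior,
and phenotypes with sex and feed-room fixed effects at a target narrow-sense
heritability.

Every ``simulate_*`` call is bit-reproducible given its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genio import GenotypeMatrix

UNKNOWN = "0"


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Pedigree:
    """Ordered (id, sire, dam) triples; ``UNKNOWN`` ("0") marks a missing parent.

    Every named parent must appear earlier in the order than its offspring,
    which also rules out any individual being its own ancestor.
    """

    records: list
    generation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for i, s, d in self.records:
            if i in seen:
                raise ValueError(f"duplicate id {i!r} in pedigree")
            for parent in (s, d):
                if parent != UNKNOWN and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {i!r} not listed before its offspring "
                        "(cyclic or unordered pedigree)"
                    )
            seen.add(i)

    @property
    def ids(self) -> list:
        return [r[0] for r in self.records]

    def parents(self, ind: str) -> tuple:
        for i, s, d in self.records:
            if i == ind:
                return s, d
        raise KeyError(ind)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Founders


@dataclass
class FounderPopulationSpec:
    """Parameters of the two divergent founder lines.

    ``ld_decay_rate`` is the per-bp decay of the latent haplotype correlation
    between adjacent markers (correlation ``exp(-rate * distance)``); 0 gives
    complete association along the chromosome, large values independence.
    """

    n_founders_per_line: int = 20
    n_chromosomes: int = 5
    markers_per_chromosome: int = 400
    chromosome_length_bp: int = 50_000_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_decay_rate: float = 5e-7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders_per_line", "n_chromosomes", "markers_per_chromosome",
                     "chromosome_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.ld_decay_rate < 0:
            raise ValueError("ld_decay_rate must be >= 0")


def _sample_haplotypes(rng, n_hap: int, freqs: np.ndarray, pos: np.ndarray,
                       decay: float) -> np.ndarray:
    """Haplotypes from a Gaussian-copula AR(1) process along the chromosome.

    A latent standard-normal series with correlation exp(-decay * d) between
    adjacent markers is thresholded at the normal quantile of each allele
    frequency, yielding marginally-correct frequencies with LD that decays
    with distance.
    """
    m = len(freqs)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    r = np.exp(-decay * np.diff(pos))
    noise = rng.standard_normal((n_hap, m - 1)) if m > 1 else None
    for k in range(1, m):
        z[:, k] = r[k - 1] * z[:, k - 1] + np.sqrt(1.0 - r[k - 1] ** 2) * noise[:, k - 1]
    thresh = norm.ppf(freqs)
    return (z < thresh).astype(np.int8)


def _unique_positions(rng, m: int, length: int) -> np.ndarray:
    """m distinct sorted bp positions in [1, length] without materializing the range."""
    if m > length:
        raise ValueError("more markers than base pairs")
    pos = np.unique(rng.integers(1, length + 1, size=m))
    while len(pos) < m:
        extra = rng.integers(1, length + 1, size=m - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def simulate_founders(spec: FounderPopulationSpec) -> GenotypeMatrix:
    """Simulate two founder lines with line-divergent allele frequencies.

    Line-specific frequencies are drawn independently per marker from
    U(maf_low, maf_high), so lines diverge on average; phased haplotypes are
    attached for downstream gene dropping. Ids are ``L1_*`` / ``L2_*``.
    """
    rng = np.random.default_rng(spec.seed)
    n_line = spec.n_founders_per_line
    chrom_blocks, maps = [], []
    for c in range(spec.n_chromosomes):
        m_c = spec.markers_per_chromosome
        pos = _unique_positions(rng, m_c, spec.chromosome_length_bp)
        hap_blocks = []
        for _line in (1, 2):
            freqs = rng.uniform(spec.maf_low, spec.maf_high, size=m_c)
            hap_blocks.append(_sample_haplotypes(rng, 2 * n_line, freqs, pos,
                                                 spec.ld_decay_rate))
        chrom_blocks.append(np.vstack(hap_blocks))
        maps.append(pd.DataFrame({"chrom": f"chr{c + 1}", "pos": pos,
                                  "a1": "A", "a2": "G"}))
    hap_flat = np.hstack(chrom_blocks)  # (2*2*n_line, total markers)
    marker_map = pd.concat(maps, ignore_index=True)
    n_total = 2 * n_line
    haps = hap_flat.reshape(n_total, 2, -1)
    codes = haps.sum(axis=1).astype(np.int8)
    ids = np.array(
        [f"L1_{i + 1}" for i in range(n_line)] + [f"L2_{i + 1}" for i in range(n_line)],
        dtype=object,
    )
    return GenotypeMatrix(codes, ids, marker_map, haplotypes=haps)


# ---------------------------------------------------------------------------
# Cross


@dataclass
class CrossDesign:
    """F1/F2 sizes and the crossover process of the gene-dropping cross."""

    n_f1: int = 50
    n_f2: int = 600
    crossover_rate_per_bp: float = 1e-8  # ~1 cM/Mb
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f1 < 2 or self.n_f2 < 1:
            raise ValueError("need n_f1 >= 2 and n_f2 >= 1")
        if self.crossover_rate_per_bp < 0:
            raise ValueError("crossover rate must be >= 0")


def _chrom_slices(marker_map: pd.DataFrame) -> list:
    out = []
    chroms = marker_map["chrom"].to_numpy()
    start = 0
    for k in range(1, len(chroms) + 1):
        if k == len(chroms) or chroms[k] != chroms[start]:
            out.append(slice(start, k))
            start = k
    return out


def _gamete(rng, haps: np.ndarray, slices, positions, rate: float) -> np.ndarray:
    """Transmit one recombinant haplotype from a parent's phased pair."""
    out = np.empty(haps.shape[1], dtype=np.int8)
    for sl in slices:
        pos = positions[sl]
        length = int(pos[-1] - pos[0]) + 1
        n_cross = rng.poisson(rate * length)
        phase = rng.integers(0, 2)
        if n_cross == 0:
            out[sl] = haps[phase, sl]
            continue
        xpos = np.sort(rng.integers(pos[0], pos[-1] + 1, size=n_cross))
        segment = phase + np.searchsorted(xpos, pos, side="right")
        choose = (segment % 2).astype(np.int8)
        block = haps[:, sl]
        out[sl] = np.where(choose == 0, block[0], block[1])
    return out


def simulate_cross(
    founders: GenotypeMatrix, design: CrossDesign, seed: int | None = None
) -> tuple[Pedigree, GenotypeMatrix]:
    """Gene-drop an F1 then an F2 generation from the two founder lines.

    Each F1 is a cross of a random line-1 sire and line-2 dam; each F2 comes
    from a random pair of distinct F1 parents. Crossovers follow a Poisson
    (exponential inter-crossover) process along each chromosome. The returned
    pedigree records every mating; the genotype matrix covers founders, F1
    and F2 with phased haplotypes attached.
    """
    if founders.haplotypes is None:
        raise ValueError("founders must carry phased haplotypes (use simulate_founders)")
    ids = list(founders.individual_ids)
    line1 = [i for i in ids if str(i).startswith("L1_")]
    line2 = [i for i in ids if str(i).startswith("L2_")]
    if not line1 or not line2:
        raise ValueError("two founder lines (L1_*/L2_*) required for an F2 cross")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    slices = _chrom_slices(founders.marker_map)
    positions = founders.marker_map["pos"].to_numpy()
    rate = design.crossover_rate_per_bp

    hap_of = {i: founders.haplotypes[k] for k, i in enumerate(ids)}
    records = [(i, UNKNOWN, UNKNOWN) for i in ids]
    generation = {i: 0 for i in ids}

    def make_offspring(name, sire, dam):
        pat = _gamete(rng, hap_of[sire], slices, positions, rate)
        mat = _gamete(rng, hap_of[dam], slices, positions, rate)
        hap_of[name] = np.stack([pat, mat])
        records.append((name, sire, dam))

    f1 = []
    for k in range(design.n_f1):
        name = f"F1_{k + 1}"
        make_offspring(name, line1[rng.integers(len(line1))], line2[rng.integers(len(line2))])
        generation[name] = 1
        f1.append(name)

    for k in range(design.n_f2):
        i, j = rng.choice(len(f1), size=2, replace=False)
        name = f"F2_{k + 1}"
        make_offspring(name, f1[i], f1[j])
        generation[name] = 2

    all_ids = [r[0] for r in records]
    haps = np.stack([hap_of[i] for i in all_ids])
    codes = haps.sum(axis=1).astype(np.int8)
    g = GenotypeMatrix(codes, np.asarray(all_ids, dtype=object),
                       founders.marker_map.reset_index(drop=True), haplotypes=haps)
    return Pedigree(records, generation), g


# ---------------------------------------------------------------------------
# Trait architectures


ARCH_KINDS = ("polygenic", "sparse_t", "normal_mixture_pi", "maf_coupled_S",
              "four_component_R")


@dataclass
class TraitArchitecture:
    """Marker-effect architecture matched to one prior family.

    ``pi`` is the proportion of markers with a NON-zero effect (this
    project's convention throughout). ``S`` couples effect variance to MAF
    via (2p(1-p))^S; ``component_weights`` are the four mixture proportions
    of the 0 / 0.01 / 0.1 / 1 variance classes.
    """

    kind: str
    h2_target: float = 0.5
    n_qtl: int | None = None
    pi: float | None = None
    S: float = 0.0
    component_weights: tuple = (0.25, 0.25, 0.25, 0.25)
    t_df: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ARCH_KINDS:
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if not (0.0 <= self.h2_target <= 1.0):
            raise ValueError("h2_target must lie in [0, 1]")
        if self.pi is not None and not (0.0 <= self.pi <= 1.0):
            raise ValueError("pi must lie in [0, 1]")
        w = np.asarray(self.component_weights, float)
        if self.kind == "four_component_R" and (len(w) != 4 or abs(w.sum() - 1) > 1e-9
                                                or (w < 0).any()):
            raise ValueError("component_weights must be 4 non-negative proportions summing to 1")


_R_GAMMA = np.array([0.0, 0.01, 0.1, 1.0])


def simulate_effects(arch: TraitArchitecture, markers: GenotypeMatrix | int,
                     seed: int = 0) -> np.ndarray:
    """Draw a marker-effect vector under the given architecture.

    ``markers`` may be a GenotypeMatrix (required for maf_coupled_S, which
    reads observed allele frequencies) or just a marker count.
    """
    if isinstance(markers, GenotypeMatrix):
        m = markers.n_markers
        freqs = markers.allele_frequency()
    else:
        m = int(markers)
        freqs = None
    rng = np.random.default_rng(seed)
    eff = np.zeros(m)

    if arch.kind == "polygenic":
        eff = rng.standard_normal(m)
    elif arch.kind == "sparse_t":
        n_qtl = arch.n_qtl if arch.n_qtl is not None else int(round((arch.pi or 0) * m))
        if n_qtl > 0:
            qtl = rng.choice(m, size=n_qtl, replace=False)
            eff[qtl] = rng.standard_t(arch.t_df, size=n_qtl)
    elif arch.kind == "normal_mixture_pi":
        pi = 1.0 if arch.pi is None else arch.pi
        nz = rng.random(m) < pi
        eff[nz] = rng.standard_normal(int(nz.sum()))
    elif arch.kind == "maf_coupled_S":
        if freqs is None:
            raise ValueError("maf_coupled_S needs a GenotypeMatrix for allele frequencies")
        pi = 1.0 if arch.pi is None else arch.pi
        nz = rng.random(m) < pi
        het = np.clip(2.0 * freqs * (1.0 - freqs), 1e-12, None)
        sd = het ** (arch.S / 2.0)
        eff[nz] = rng.standard_normal(int(nz.sum())) * sd[nz]
    elif arch.kind == "four_component_R":
        comp = rng.choice(4, size=m, p=np.asarray(arch.component_weights, float))
        sd = np.sqrt(_R_GAMMA[comp])
        eff = rng.standard_normal(m) * sd

    if arch.h2_target > 0 and not np.any(eff):
        raise ValueError("architecture yields no non-zero effects but h2_target > 0")
    return eff


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass
class FixedEffectSpec:
    """Additive categorical shifts: two sexes and ``n_rooms`` feed rooms."""

    sex_levels: tuple = ("M", "F")
    sex_shift: float = 0.0           # added to the second sex level
    room_shifts: tuple = (0.0, 0.0)  # one shift per feed room
    intercept: float = 0.0

    @property
    def n_rooms(self) -> int:
        return len(self.room_shifts)


@dataclass
class PhenotypeTable:
    """Trait observations plus fixed-effect levels, one row per individual.

    Wraps a DataFrame with an ``id`` column, categorical factor columns and
    one column per trait (NaN = missing observation).
    """

    df: pd.DataFrame
    trait_cols: list
    factor_cols: list = field(default_factory=lambda: ["sex", "feed_room"])
    true_genetic_values: pd.Series | None = None

    def __post_init__(self) -> None:
        if "id" not in self.df.columns:
            raise ValueError("phenotype table needs an 'id' column")
        if self.df["id"].duplicated().any():
            raise ValueError("duplicate ids in phenotype table")

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy(dtype=object)

    def trait(self, name: str) -> pd.Series:
        return self.df.set_index("id")[name]


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
    h2_target: float,
    fixed: FixedEffectSpec | None = None,
    seed: int = 0,
    trait_name: str = "trait",
) -> PhenotypeTable:
    """Phenotypes y = intercept + sex/room shifts + g + e at a target h2.

    Genetic values are g = (M - 2p) @ effects with observed frequencies p.
    The residual variance is set from the REALIZED var(g) of this sample,
    var(e) = var(g)(1 - h2)/h2, so parameter-recovery tests are sharp at
    moderate n; h2_target = 0 zeroes the genetic contribution entirely and
    uses a unit residual.
    """
    if not (0.0 <= h2_target < 1.0):
        raise ValueError("h2_target must lie in [0, 1)")
    effects = np.asarray(effects, float)
    if h2_target > 0 and not np.any(effects):
        raise ValueError("all-zero effects cannot reach h2_target > 0")
    fixed = fixed or FixedEffectSpec()
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals

    p = genotypes.allele_frequency()
    Z = genotypes.dosage() - 2.0 * np.nan_to_num(p)
    g = Z @ effects if h2_target > 0 else np.zeros(n)
    var_g = float(np.var(g))
    if h2_target > 0:
        if var_g <= 0:
            raise ValueError("realized genetic variance is zero; cannot hit h2_target")
        var_e = var_g * (1.0 - h2_target) / h2_target
    else:
        var_e = 1.0
    e = rng.standard_normal(n) * np.sqrt(var_e)

    sex = rng.integers(0, 2, size=n)
    room = rng.integers(0, fixed.n_rooms, size=n)
    y = (fixed.intercept + g + e
         + sex * fixed.sex_shift
         + np.asarray(fixed.room_shifts, float)[room])

    df = pd.DataFrame(
        {
            "id": genotypes.individual_ids,
            "sex": np.asarray(fixed.sex_levels, dtype=object)[sex],
            "feed_room": np.array([f"room{r + 1}" for r in room], dtype=object),
            trait_name: y,
        }
    )
    return PhenotypeTable(
        df, trait_cols=[trait_name],
        true_genetic_values=pd.Series(g, index=df["id"]),
    )


# ---------------------------------------------------------------------------
# Derived traits


def derive_traits(weights: dict | None = None,
                  morphology: tuple | None = None) -> dict:
    """Growth and breast-morphology traits derived from raw measurements.

    ``weights`` maps day-of-age to body weight (g); every ordered pair of
    measured days (a < b) yields an average daily gain
    ADG_a-b = (BW_b - BW_a) / (b - a + 1) in g/day.  ``morphology`` is
    (KL, BMW, BMT) in cm, yielding the breast-muscle volume proxy
    BMV = KL x BMW x BMT in cm^3.  A missing later-day weight makes the
    derived ADG missing (NaN).
    """
    out: dict = {}
    if weights:
        days = sorted(weights)
        for ai, a in enumerate(days):
            if weights[a] is not None and weights[a] < 0:
                raise ValueError("weights must be non-negative")
            for b in days[ai + 1:]:
                if b <= a:
                    raise ValueError("end day must exceed start day")
                wa, wb = weights[a], weights[b]
                if wa is None or wb is None or np.isnan(wa) or np.isnan(wb):
                    out[f"ADG_{a}-{b}"] = float("nan")
                else:
                    out[f"ADG_{a}-{b}"] = (wb - wa) / (b - a + 1)
    if morphology is not None:
        kl, bmw, bmt = morphology
        out["BMV"] = kl * bmw * bmt
    return out


# ---------------------------------------------------------------------------
# Miniature study fixture


@dataclass
class StudyFixture:
    """A complete miniature study: pedigree, genotypes, phenotypes, truth."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix         # all individuals
    genotyped: GenotypeMatrix         # the "genotyped" subset
    phenotypes: PhenotypeTable
    effects: np.ndarray
    true_genetic_values: pd.Series


def make_study_fixture(
    n_f2: int = 600,
    markers_per_chromosome: int = 400,
    n_chromosomes: int = 5,
    h2: float = 0.5,
    architecture: TraitArchitecture | None = None,
    fixed: FixedEffectSpec | None = None,
    prop_ungenotyped: float = 0.0,
    n_founders_per_line: int = 20,
    n_f1: int = 50,
    ld_decay_rate: float = 5e-7,
    seed: int = 0,
) -> StudyFixture:
    """One self-contained synthetic study (default: 600 F2, 2000 SNPs on 5 chromosomes).

    Phenotypes are generated for the F2 generation; ``prop_ungenotyped``
    removes that fraction of phenotyped F2s from the "genotyped" set (they
    stay in the pedigree), emulating a single-step scenario.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    founders = simulate_founders(FounderPopulationSpec(
        n_founders_per_line=n_founders_per_line,
        n_chromosomes=n_chromosomes,
        markers_per_chromosome=markers_per_chromosome,
        ld_decay_rate=ld_decay_rate,
        seed=sub(),
    ))
    ped, geno = simulate_cross(founders, CrossDesign(n_f1=n_f1, n_f2=n_f2, seed=sub()))
    f2_ids = [i for i in geno.individual_ids if str(i).startswith("F2_")]
    f2 = geno.subset_individuals(f2_ids)
    arch = architecture or TraitArchitecture("polygenic", h2_target=h2)
    arch.h2_target = h2
    effects = simulate_effects(arch, f2, seed=sub())
    fixed = fixed or FixedEffectSpec(sex_shift=20.0, room_shifts=(0.0, 10.0))
    pheno = simulate_phenotypes(f2, effects, h2, fixed, seed=sub())

    if prop_ungenotyped > 0:
        n_drop = int(round(prop_ungenotyped * len(f2_ids)))
        drop = set(rng.choice(f2_ids, size=n_drop, replace=False))
        geno_ids = [i for i in f2_ids if i not in drop]
    else:
        geno_ids = f2_ids
    return StudyFixture(
        pedigree=ped,
        genotypes=geno,
        genotyped=geno.subset_individuals(geno_ids),
        phenotypes=pheno,
        effects=effects,
        true_genetic_values=pheno.true_genetic_values,
    )
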