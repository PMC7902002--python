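"""Founder genome simulation, meiosis and doubled-haploid production.

Founder haplotypes for the two component crops are drawn from a neutral
coalescent with a piecewise demographic history (small recent effective
population size growing linearly backward in time to a large ancestral
size), using :mod:`msprime`. Downstream gamete formation uses a
no-interference crossover model: the number of crossovers per chromosome is
Poisson with mean equal to the chromosome's genetic map length, and
crossover positions are uniform on the genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

__all__ = [
    "Demography",
    "GenomeParams",
    "SiteMap",
    "FounderSet",
    "derive_recombination_rate",
    "format_rate_2sf",
    "simulate_founders",
    "meiosis",
    "gametes",
    "make_dh",
    "make_dh_batch",
    "cross_dh",
]


@dataclass(frozen=True)
class Demography:
    """Piecewise-linear effective population size history.

    Ne equals ``ne_recent`` at present and increases linearly (backward in
    time) to ``ne_ancient`` at ``t_ancient`` generations ago, remaining
    constant before that. The linear ramp is approximated by
    ``n_epochs`` piecewise-constant epochs for the coalescent engine.
    """

    ne_recent: float = 50.0
    ne_ancient: float = 32_000.0
    t_ancient: float = 100_000.0
    n_epochs: int = 20

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=self.ne_recent)
        if self.ne_ancient != self.ne_recent:
            times = np.linspace(0.0, self.t_ancient, self.n_epochs + 1)[1:]
            for t in times:
                ne = self.ne_recent + (self.ne_ancient - self.ne_recent) * t / self.t_ancient
                dem.add_population_parameters_change(time=t, initial_size=ne, population="pop")
        return dem


def derive_recombination_rate(genetic_length: float, physical_length: float) -> float:
    """Per-bp recombination rate as the exact ratio of map to physical length.

    Parameters
    ----------
    genetic_length
        Chromosome genetic length in Morgans.
    physical_length
        Chromosome physical length in base pairs.
    """
    if genetic_length <= 0 or physical_length <= 0:
        raise ValueError(
            f"chromosome lengths must be positive, got genetic_length={genetic_length}, "
            f"physical_length={physical_length}"
        )
    return genetic_length / physical_length


def format_rate_2sf(rate: float) -> str:
    """Display helper: format a rate to two significant figures (e.g. '1.8e-09')."""
    return f"{float(f'{rate:.1e}'):.1e}"


@dataclass(frozen=True)
class GenomeParams:
    """Parameters of one (hypothetical) crop genome.

    Defaults correspond to the full-scale genome: 10 chromosome pairs, each
    1.43 Morgans and 8x10^8 bp, mutation rate 2x10^-9 per bp, 1,000 QTN and
    2,000 SNP-array markers per chromosome.
    """

    n_chromosomes: int = 10
    genetic_length: float = 1.43
    physical_length: float = 8e8
    mutation_rate: float = 2e-9
    n_qtn_per_chr: int = 1000
    n_snp_per_chr: int = 2000
    demography: Demography = field(default_factory=Demography)

    def __post_init__(self) -> None:
        # triggers validation
        derive_recombination_rate(self.genetic_length, self.physical_length)
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")

    @property
    def recombination_rate(self) -> float:
        """Per-bp recombination rate (genetic length / physical length)."""
        return derive_recombination_rate(self.genetic_length, self.physical_length)


def desk_genome_params() -> GenomeParams:
    """Scaled-down genome preset for desk-scale runs.

    Two chromosomes with the full per-chromosome map length (1.43 M) but a
    reduced physical length (1 Mb) and a correspondingly raised mutation
    rate, carrying 100 QTN and 200 SNP markers each. This preserves the
    shape of the genetic architecture (polygenic trait, genome-wide marker
    panel denser than the trait) at a small fraction of the cost.
    """
    return GenomeParams(
        n_chromosomes=2,
        genetic_length=1.43,
        physical_length=1e6,
        mutation_rate=2e-6,
        n_qtn_per_chr=100,
        n_snp_per_chr=200,
    )


@dataclass(frozen=True)
class SiteMap:
    """Genomic coordinates and roles of the retained polymorphic sites.

    Sites are ordered by (chromosome, position). ``pos_morgan`` is the
    position on the genetic map of its chromosome, in Morgans from the
    chromosome start; ``is_qtn`` flags causal sites, the remainder being
    the SNP marker array. QTN and SNP sets are disjoint by construction.
    """

    chrom: np.ndarray          # (L,) int16
    pos_bp: np.ndarray         # (L,) float64
    pos_morgan: np.ndarray     # (L,) float64
    is_qtn: np.ndarray         # (L,) bool
    genetic_length: float      # Morgans per chromosome

    @property
    def n_sites(self) -> int:
        return self.chrom.size

    @property
    def qtn_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtn)

    @property
    def snp_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtn)

    def chromosome_slices(self) -> list[slice]:
        """Contiguous index ranges of each chromosome (sites are sorted)."""
        out = []
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out


@dataclass
class FounderSet:
    """Founder doubled-haploid lines of one crop.

    Each founder carries a single distinct haplotype (stored once); after
    DH conversion the individual is fully homozygous, so its genotype is
    the haplotype duplicated.
    """

    crop_id: str
    haplotypes: np.ndarray     # (n_founders, L) uint8
    site_map: SiteMap

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    def diploid_haplotypes(self) -> np.ndarray:
        """(n, 2, L) genotype array with both haplotypes identical (DH)."""
        return np.repeat(self.haplotypes[:, None, :], 2, axis=1)

    def dosages(self, sites: np.ndarray | None = None) -> np.ndarray:
        """Allele dosages (0/2 for DH lines), optionally at a site subset."""
        h = self.haplotypes if sites is None else self.haplotypes[:, sites]
        return 2.0 * h

    def save(self, path: str) -> None:
        sm = self.site_map
        np.savez_compressed(
            path, crop_id=self.crop_id, haplotypes=self.haplotypes,
            chrom=sm.chrom, pos_bp=sm.pos_bp, pos_morgan=sm.pos_morgan,
            is_qtn=sm.is_qtn, genetic_length=sm.genetic_length,
        )

    @classmethod
    def load(cls, path: str) -> "FounderSet":
        z = np.load(path, allow_pickle=False)
        sm = SiteMap(
            chrom=z["chrom"], pos_bp=z["pos_bp"], pos_morgan=z["pos_morgan"],
            is_qtn=z["is_qtn"], genetic_length=float(z["genetic_length"]),
        )
        return cls(crop_id=str(z["crop_id"]), haplotypes=z["haplotypes"], site_map=sm)


def simulate_founders(
    params: GenomeParams,
    n_founders: int,
    seed: int,
    crop_id: str = "A",
) -> FounderSet:
    """Simulate ``n_founders`` founder DH lines for one crop.

    One coalescent tree sequence is simulated per chromosome under the
    configured demography; ``n_qtn_per_chr`` + ``n_snp_per_chr`` sites are
    then sampled uniformly without replacement from the sites segregating
    among the founder haplotypes, and roles (QTN vs SNP) are assigned at
    random within the sample. Founders are sampled as single haplotypes,
    i.e. directly as the DH conversion of a Hardy-Weinberg base individual.

    The two crops are simulated independently: call this twice with
    different seeds.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    dem = params.demography.to_msprime()

    n_keep = params.n_qtn_per_chr + params.n_snp_per_chr
    chroms, pos_bps, is_qtns, haps = [], [], [], []
    for c in range(params.n_chromosomes):
        anc_seed = int(rng.integers(1, 2**31 - 1))
        mut_seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=n_founders,
            ploidy=1,
            demography=dem,
            sequence_length=params.physical_length,
            recombination_rate=params.recombination_rate,
            random_seed=anc_seed,
        )
        mts = msprime.sim_mutations(
            ts, rate=params.mutation_rate, random_seed=mut_seed,
            model=msprime.BinaryMutationModel(),
        )
        gmat = mts.genotype_matrix()          # (sites, n_founders), 0/1
        seg = np.flatnonzero((gmat.min(axis=1) == 0) & (gmat.max(axis=1) >= 1))
        if seg.size < n_keep:
            raise ValueError(
                f"chromosome {c}: only {seg.size} segregating sites among founders "
                f"but {n_keep} QTN+SNP requested; increase the mutation rate or "
                f"use a scaled genome preset"
            )
        chosen = np.sort(rng.choice(seg, size=n_keep, replace=False))
        roles = np.zeros(n_keep, dtype=bool)
        roles[rng.choice(n_keep, size=params.n_qtn_per_chr, replace=False)] = True
        pos = mts.sites_position[chosen]
        chroms.append(np.full(n_keep, c, dtype=np.int16))
        pos_bps.append(pos)
        is_qtns.append(roles)
        haps.append(np.ascontiguousarray(gmat[chosen].T.astype(np.uint8)))

    pos_bp = np.concatenate(pos_bps)
    site_map = SiteMap(
        chrom=np.concatenate(chroms),
        pos_bp=pos_bp,
        pos_morgan=pos_bp * params.recombination_rate,
        is_qtn=np.concatenate(is_qtns),
        genetic_length=params.genetic_length,
    )
    return FounderSet(
        crop_id=crop_id,
        haplotypes=np.concatenate(haps, axis=1),
        site_map=site_map,
    )


def gametes(
    parent: np.ndarray,
    site_map: SiteMap,
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Form ``n`` recombinant gametes from a (2, L) parent genotype.

    Crossovers per chromosome are Poisson with mean equal to the genetic
    map length, placed uniformly on the map (no interference). Returns an
    (n, L) uint8 array.
    """
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 2 or parent.shape[1] != site_map.n_sites:
        raise ValueError(
            f"parent genotype must have shape (2, {site_map.n_sites}), got {parent.shape}"
        )
    L = site_map.n_sites
    out = np.empty((n, L), dtype=np.uint8)
    gl = site_map.genetic_length
    slices = site_map.chromosome_slices()
    starts = rng.integers(0, 2, size=(n, len(slices)))
    n_cross = rng.poisson(gl, size=(n, len(slices)))
    for g in range(n):
        for ci, sl in enumerate(slices):
            pos = site_map.pos_morgan[sl]
            k = n_cross[g, ci]
            if k == 0:
                src = np.full(pos.size, starts[g, ci])
            else:
                xp = np.sort(rng.uniform(0.0, gl, size=k))
                src = (starts[g, ci] + np.searchsorted(xp, pos)) % 2
            out[g, sl] = np.where(src == 0, parent[0, sl], parent[1, sl])
    return out


def meiosis(parent: np.ndarray, site_map: SiteMap, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete (a (L,) haplotype) from a (2, L) parent."""
    return gametes(parent, site_map, rng, n=1)[0]


def make_dh(f1: np.ndarray, site_map: SiteMap, rng: np.random.Generator) -> np.ndarray:
    """One doubled-haploid genotype: a single gamete duplicated, (2, L)."""
    g = meiosis(f1, site_map, rng)
    return np.stack([g, g])


def make_dh_batch(
    f1: np.ndarray, site_map: SiteMap, rng: np.random.Generator, n: int
) -> np.ndarray:
    """``n`` doubled haploids from one F1, as an (n, 2, L) array."""
    g = gametes(f1, site_map, rng, n=n)
    return np.repeat(g[:, None, :], 2, axis=1)


def cross_dh(mother: np.ndarray, father: np.ndarray) -> np.ndarray:
    """F1 genotype of a bi-parental cross between two DH lines.

    DH parents are fully homozygous, so each transmits its unique haplotype
    deterministically; the F1 is (maternal haplotype, paternal haplotype).
    """
    mother = np.asarray(mother)
    father = np.asarray(father)
    if not (mother[0] == mother[1]).all() or not (father[0] == father[1]).all():
        raise ValueError("cross_dh expects fully homozygous (DH) parents")
    return np.stack([mother[0], father[0]])
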