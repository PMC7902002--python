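"""Year-by-year orchestration of the intercrop breeding programs.

The pipeline advances one calendar year at a time. A year proceeds in a
fixed order:

1. genomic model fits (GS arms only) on the 5-year training window of
   records accumulated up to the previous year;
2. field stages: DH production from last year's crosses, then PYT, GIA1,
   GIA2 (conventional skeleton) or the grid stage (grid program), then
   the shared SIA1 and SIA2 intercrop stages, each phenotyped at its
   (reps, h^2) and logged as training records;
3. selections that populate next year's stages, probe-variety and
   crossing-block updates;
4. new bi-parental crosses from the updated block.

Stage schedule (conventional): cross -> DH single plants -> PYT monocrop
trial -> GIA1 (tested against one probe variety of the other crop) ->
GIA2 (three probes) -> SIA1 (all pairwise combinations of the selected
lines of the two crops) -> SIA2 -> release of the best combination. The
grid program replaces PYT/GIA1/GIA2 by one grid stage of field-tested
pairs sampled from the gGIA-selected DH grid.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import ProgramDesign, StageSpec
from .genome import FounderSet, SiteMap, gametes
from .gsmodels import (
    GridMarkerEffects,
    GridTrainingSet,
    MarkerEffects,
    TrainingSet,
    VarianceComponents,
    fit_grid_rrblup,
    fit_multitrait_rrblup,
    pair_ggia_matrix,
    predict_ggia,
    regularize_variance_components,
    true_variance_components,
)
from .traits import TraitArchitecture, genetic_values, stage_mean_error_variance

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "PairSet",
    "CropState",
    "PipelineState",
    "initialize_state",
    "advance_year",
    "run_burnin",
    "run_future",
    "make_crosses_random",
    "make_crosses_max_avoidance",
    "select_parents_truncation",
    "grid_sample_and_select",
    "build_training_window",
    "build_grid_training_window",
    "pair_universe_size",
    "conventional_window_counts",
    "grid_window_counts",
    "grid_init_counts",
]

CROPS = ("A", "B")


# ---------------------------------------------------------------------------
# containers


@dataclass
class Cohort:
    """A set of DH genotypes of one crop at one point in the pipeline."""

    ids: np.ndarray           # (n,) int64
    haplo: np.ndarray         # (n, 2, L) uint8
    family: np.ndarray        # (n,) int64 cross-of-origin identifier
    a_m: np.ndarray           # true monocrop genetic values
    a_ic: np.ndarray          # true intercrop genetic values
    birth_year: np.ndarray    # (n,) int32
    pheno: np.ndarray | None = None
    ggia: np.ndarray | None = None
    entry_year: np.ndarray | None = None   # crossing-block residence tag

    def __len__(self) -> int:
        return self.ids.size

    def take(self, idx: np.ndarray) -> "Cohort":
        def sub(x):
            return None if x is None else x[idx]
        return Cohort(
            ids=self.ids[idx], haplo=self.haplo[idx], family=self.family[idx],
            a_m=self.a_m[idx], a_ic=self.a_ic[idx], birth_year=self.birth_year[idx],
            pheno=sub(self.pheno), ggia=sub(self.ggia), entry_year=sub(self.entry_year),
        )

    def dosage(self, sites: np.ndarray) -> np.ndarray:
        """Allele dosages (0/2 for DH lines) at a site subset, as float."""
        return self.haplo[:, :, sites].sum(axis=1).astype(float)


def concat_cohorts(a: Cohort, b: Cohort) -> Cohort:
    def cat(x, y):
        return None if x is None or y is None else np.concatenate([x, y])
    return Cohort(
        ids=np.concatenate([a.ids, b.ids]),
        haplo=np.concatenate([a.haplo, b.haplo]),
        family=np.concatenate([a.family, b.family]),
        a_m=np.concatenate([a.a_m, b.a_m]),
        a_ic=np.concatenate([a.a_ic, b.a_ic]),
        birth_year=np.concatenate([a.birth_year, b.birth_year]),
        pheno=cat(a.pheno, b.pheno),
        ggia=cat(a.ggia, b.ggia),
        entry_year=cat(a.entry_year, b.entry_year),
    )


@dataclass
class PairSet:
    """Intercrop combinations (one genotype per crop) at a pair-tested stage."""

    ids_A: np.ndarray
    ids_B: np.ndarray
    a_ic_A: np.ndarray
    a_ic_B: np.ndarray
    pheno: np.ndarray | None = None

    def __len__(self) -> int:
        return self.ids_A.size

    def take(self, idx: np.ndarray) -> "PairSet":
        return PairSet(
            ids_A=self.ids_A[idx], ids_B=self.ids_B[idx],
            a_ic_A=self.a_ic_A[idx], a_ic_B=self.a_ic_B[idx],
            pheno=None if self.pheno is None else self.pheno[idx],
        )


@dataclass
class CropState:
    """Per-crop pipeline state.

    ``to_pyt``/``to_gia1``/``to_gia2`` hold the cohorts *entering* those
    stages this year (selected at the end of the previous year)."""

    crop: str
    site_map: SiteMap
    qtn_idx: np.ndarray
    snp_idx: np.ndarray
    arch: TraitArchitecture
    block: Cohort
    probes: Cohort            # probes.ids[0] serves GIA1, probes.ids[1:] serve GIA2
    pending: list             # FIFO of cross batches; DH production takes 2 years,
                              # so each batch [(mother_hap, father_hap, mid, fid), ...]
                              # ripens two positions after it is appended
    next_id: int
    dh: Cohort | None = None
    to_pyt: Cohort | None = None
    to_gia1: Cohort | None = None
    to_gia2: Cohort | None = None
    incoming_parents: Cohort | None = None  # GIA1 selections awaiting block entry
    effects: MarkerEffects | None = None


@dataclass
class PipelineState:
    """Full simulation state shared by the two component crops."""

    design: ProgramDesign
    grid_design: ProgramDesign | None
    burnin_years: int
    year: int
    crops: dict[str, CropState]
    sia1_pairs: PairSet | None = None
    sia2_pairs: PairSet | None = None
    records: list = field(default_factory=list)
    conv_geno: dict = field(default_factory=lambda: {c: {} for c in CROPS})
    grid_geno: dict = field(default_factory=lambda: {c: {} for c in CROPS})
    value_store: dict = field(default_factory=lambda: {c: {} for c in CROPS})
    pedigree: dict = field(default_factory=lambda: {c: {} for c in CROPS})
    metrics: list = field(default_factory=list)
    released: list = field(default_factory=list)
    grid_effects: GridMarkerEffects | None = None
    ma_generation: int = 0
    next_family: int = 0

    def snapshot(self) -> "PipelineState":
        """Deep copy used to branch program arms off a shared burn-in."""
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# crossing schemes


def pair_universe_size(block_size: int) -> int:
    """Number of distinct unordered parent pairs in a crossing block."""
    return math.comb(block_size, 2)


def make_crosses_random(
    block_size: int, n_crosses: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample distinct unordered parent pairs uniformly without replacement.

    Returns an (n_crosses, 2) array of indices into the crossing block.
    """
    total = pair_universe_size(block_size)
    if n_crosses > total:
        raise ValueError(
            f"cannot make {n_crosses} distinct crosses from {block_size} parents "
            f"({total} possible pairs)"
        )
    i, j = np.triu_indices(block_size, k=1)
    sel = rng.choice(total, size=n_crosses, replace=False)
    return np.column_stack([i[sel], j[sel]])


def make_crosses_max_avoidance(
    families: np.ndarray, generation: int, n_crosses: int
) -> np.ndarray:
    """Relative-avoiding circular pairing of a family-sorted crossing block.

    The ``2 * n_crosses`` parents must be ordered by family. The block is
    split into two halves and slot ``k`` of the first half is crossed to
    slot ``(k + generation) mod n/2`` of the second half, so every parent
    contributes to exactly one cross per round (the equal-contribution
    property) and -- families being contiguous in the ordering -- the two
    mates of a cross come from maximally separated positions of the family
    spectrum. Any same-family pairing left by the shift (a family larger
    than half the block) is resolved by greedy swaps within the second
    half where possible. The generation counter rotates the shift so the
    same two families do not meet cross after cross, deferring the
    re-meeting of relatives in the spirit of a maximum-avoidance scheme.

    Returns (n_crosses, 2) index pairs into the parent list.
    """
    families = np.asarray(families)
    n = families.size
    if n != 2 * n_crosses:
        raise ValueError(
            f"max-avoidance pairing needs 2 parents per cross, got {n} parents "
            f"for {n_crosses} crosses"
        )
    half = n // 2
    left = np.arange(half)
    right = np.roll(np.arange(half, n), -(generation % half))
    for k in range(half):
        if families[left[k]] != families[right[k]]:
            continue
        for m in range(half):
            if (families[left[m]] != families[right[k]]
                    and families[left[k]] != families[right[m]]):
                right[k], right[m] = right[m], right[k]
                break
    return np.column_stack([left, right])


def select_parents_truncation(
    cohort: Cohort, scores: np.ndarray, n_parents: int
) -> Cohort:
    """The ``n_parents`` best lines by score, ordered by family for pairing.

    Ties are broken by genotype id; the returned cohort is sorted by
    (family, score rank), the ordering :func:`make_crosses_max_avoidance`
    expects.
    """
    idx = _top_idx(scores, cohort.ids, n_parents)
    order = np.lexsort((cohort.ids[idx], -scores[idx], cohort.family[idx]))
    return cohort.take(idx[order])


# ---------------------------------------------------------------------------
# selection helpers


def _top_idx(scores: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k best scores, ties broken by genotype id."""
    return np.lexsort((ids, -scores))[:k]


def _select_dh_within_family(
    cohort: Cohort, scores: np.ndarray, n_total: int
) -> np.ndarray:
    """Best lines per cross, equal quota per family, remainder filled overall."""
    fam = cohort.family
    uniq = np.unique(fam)
    quota = n_total // uniq.size
    chosen: list[int] = []
    for f in uniq:
        members = np.flatnonzero(fam == f)
        ranked = members[np.lexsort((cohort.ids[members], -scores[members]))]
        chosen.extend(ranked[:quota].tolist())
    if len(chosen) < n_total:
        left = np.setdiff1d(np.arange(len(cohort)), np.array(chosen))
        ranked = left[np.lexsort((cohort.ids[left], -scores[left]))]
        chosen.extend(ranked[: n_total - len(chosen)].tolist())
    return np.array(sorted(chosen))


# ---------------------------------------------------------------------------
# bookkeeping


def _record(state: PipelineState, *, year: int, stage: str, trait: str,
            crop: str | None, id=None, id_A=None, id_B=None,
            value: float, resid_var: float, reps: int) -> None:
    state.records.append({
        "year": year, "stage": stage, "trait": trait, "crop": crop,
        "id": id, "id_A": id_A, "id_B": id_B, "value": float(value),
        "resid_var": float(resid_var), "reps": reps,
    })


def _store_genotypes(store: dict, cs: CropState, cohort: Cohort, year: int,
                     value_store: dict) -> None:
    dos = cohort.dosage(cs.snp_idx).astype(np.float32)
    for i, g in enumerate(cohort.ids):
        store[int(g)] = (year, dos[i])
        value_store[int(g)] = (float(cohort.a_m[i]), float(cohort.a_ic[i]))


def _new_cohort_from_crosses(
    state: PipelineState, cs: CropState, year: int, total_dh: int,
    rng: np.random.Generator,
) -> Cohort:
    """Produce this year's DH cohort from last year's crosses.

    The target total is distributed as evenly as possible over the ripe
    cross batch, whose crosses can outnumber the design's in the
    transition years right after a program switch."""
    pending = cs.pending.pop(0)
    n_cross = len(pending)
    base, rem = divmod(total_dh, n_cross)
    haps, fams, mids, fids = [], [], [], []
    for k, (mh, fh, mid, fid) in enumerate(pending):
        n_dh = base + (1 if k < rem else 0)
        if n_dh == 0:
            continue
        f1 = np.stack([mh, fh])
        haps.append(gametes(f1, cs.site_map, rng, n=n_dh))
        fams.append(np.full(n_dh, state.next_family + k, dtype=np.int64))
        mids.append(np.full(n_dh, mid, dtype=np.int64))
        fids.append(np.full(n_dh, fid, dtype=np.int64))
    if cs.crop == CROPS[-1]:
        state.next_family += n_cross
    hap1 = np.concatenate(haps)
    haplo = np.repeat(hap1[:, None, :], 2, axis=1)
    n = haplo.shape[0]
    ids = np.arange(cs.next_id, cs.next_id + n, dtype=np.int64)
    cs.next_id += n
    a_m, a_ic = genetic_values(hap1[:, cs.qtn_idx].astype(float) * 2.0, cs.arch)
    mid_all, fid_all = np.concatenate(mids), np.concatenate(fids)
    ped = state.pedigree[cs.crop]
    for i, g in enumerate(ids):
        ped[int(g)] = (int(mid_all[i]), int(fid_all[i]), year)
    return Cohort(
        ids=ids, haplo=haplo, family=np.concatenate(fams),
        a_m=a_m, a_ic=a_ic,
        birth_year=np.full(n, year, dtype=np.int32),
    )


# ---------------------------------------------------------------------------
# training windows


def _window_years(year: int, window: int) -> tuple[int, int]:
    return year - window, year - 1


def build_training_window(state: PipelineState, crop: str, year: int) -> TrainingSet:
    """Training data for the multi-trait model of one crop at ``year``.

    Contains the SNP genotypes of the last 5 PYT cohorts and all
    PYT/GIA1/GIA2 records in that span belonging to those genotypes. Under
    the stage-lag schedule a cohort acquires its GIA1 record one year, and
    its GIA2 record two years, after its PYT year, so records of cohorts
    genotyped before the window opened are excluded along with their
    genotypes.
    """
    lo, hi = _window_years(year, state.design.window_years)
    store = state.conv_geno[crop]
    items = sorted((y, g) for g, (y, _) in store.items() if lo <= y <= hi)
    if not items:
        raise ValueError(f"no genotyped training cohorts in years {lo}..{hi}")
    ids = np.array([g for _, g in items], dtype=np.int64)
    dosage = np.stack([store[int(g)][1] for g in ids]).astype(float)
    known = set(ids.tolist())
    rec = [r for r in state.records
           if r["crop"] == crop and r["stage"] in ("PYT", "GIA1", "GIA2")
           and lo <= r["year"] <= hi and r["id"] in known]
    values = state.value_store[crop]
    a = np.array([values[int(g)] for g in ids])
    return TrainingSet(
        crop=crop, geno_ids=ids, dosage=dosage,
        records=pd.DataFrame(rec), a_m=a[:, 0], a_ic=a[:, 1],
    )


def build_grid_training_window(state: PipelineState, year: int) -> GridTrainingSet:
    """Training data for the grid model at ``year``: the last 5 years of
    grid-stage genotypes per crop plus all grid/SIA1/SIA2 pair records in
    that span (records of pairs whose members left the genotype window are
    dropped inside the fit, with a logged count)."""
    design = state.design if state.design.kind == "grid" else state.grid_design
    lo, hi = _window_years(year, design.window_years)
    ids, dosage, a_ic = {}, {}, {}
    for crop in CROPS:
        store = state.grid_geno[crop]
        items = sorted((y, g) for g, (y, _) in store.items() if lo <= y <= hi)
        if not items:
            raise ValueError(f"no grid-stage genotypes for crop {crop} in years {lo}..{hi}")
        ids[crop] = np.array([g for _, g in items], dtype=np.int64)
        dosage[crop] = np.stack([store[int(g)][1] for g in ids[crop]]).astype(float)
        a_ic[crop] = np.array([state.value_store[crop][int(g)][1] for g in ids[crop]])
    rec = [r for r in state.records
           if r["stage"] in ("GRID", "SIA1", "SIA2") and lo <= r["year"] <= hi]
    return GridTrainingSet(
        geno_ids=ids, dosage=dosage, records=pd.DataFrame(rec), a_ic=a_ic,
    )


def conventional_window_counts(design: ProgramDesign) -> tuple[int, int]:
    """(genotypes, records) in a steady-state conventional training window.

    Five PYT cohorts are genotyped; the stage-lag schedule leaves 4 of
    them with GIA1 records and 3 with GIA2 records inside the window.
    """
    w = design.window_years
    genotypes = w * design.pyt.entries
    records = (w * design.pyt.entries
               + (w - 1) * design.gia1.entries
               + (w - 2) * design.gia2.entries)
    return genotypes, records


def grid_window_counts(design: ProgramDesign) -> tuple[int, int]:
    """(genotypes per crop, records) in a steady-state grid training window."""
    w = design.window_years
    genotypes = w * design.grid_keep
    records = w * (design.grid.entries + design.sia1.entries + design.sia2.entries)
    return genotypes, records


def grid_init_counts(design: ProgramDesign) -> tuple[int, int]:
    """(genotypes per crop, records) after the grid initialization years."""
    w = design.window_years
    return w * design.init_keep, w * design.init_keep**2


# ---------------------------------------------------------------------------
# grid stage


def grid_sample_and_select(
    ggia_A: np.ndarray,
    ggia_B: np.ndarray,
    ids_A: np.ndarray,
    ids_B: np.ndarray,
    n_field: int,
    n_advance: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample field-test pairs and pick the best-predicted combinations.

    From the full n_A x n_B grid of candidate intercrop pairs, ``n_field``
    pairs are sampled uniformly without replacement for field testing, and
    the pair-gGIAs of *all* grid cells are ranked to advance the best
    ``n_advance`` combinations. Returns (field_pairs, advance_pairs) as
    (k, 2) index arrays into (ids_A, ids_B); ties break by (id_A, id_B).
    """
    nA, nB = ggia_A.size, ggia_B.size
    total = nA * nB
    if n_field > total:
        raise ValueError(f"cannot field-test {n_field} pairs from a {nA}x{nB} grid")
    flat = rng.choice(total, size=n_field, replace=False)
    field_pairs = np.column_stack(np.unravel_index(flat, (nA, nB)))
    pg = pair_ggia_matrix(ggia_A, ggia_B).ravel()
    ia, ib = np.unravel_index(np.arange(total), (nA, nB))
    order = np.lexsort((ids_B[ib], ids_A[ia], -pg))[:n_advance]
    return field_pairs, np.column_stack([ia[order], ib[order]])


# ---------------------------------------------------------------------------
# within-year pieces


def _fit_conventional_models(state: PipelineState, year: int) -> None:
    for crop in CROPS:
        cs = state.crops[crop]
        ts = build_training_window(state, crop, year)
        vc = regularize_variance_components(
            true_variance_components(ts.a_m, ts.a_ic))
        cs.effects = fit_multitrait_rrblup(ts, vc)


def _fit_grid_model(state: PipelineState, year: int) -> GridMarkerEffects:
    ts = build_grid_training_window(state, year)
    G = np.diag([max(float(np.var(ts.a_ic[c])), 1e-6) for c in CROPS])
    return fit_grid_rrblup(ts, VarianceComponents(G=G))


def _ggia(cs: CropState, cohort: Cohort, effects) -> np.ndarray:
    dos = cohort.dosage(cs.snp_idx)
    if isinstance(effects, GridMarkerEffects):
        return predict_ggia(dos, effects, crop=cs.crop)
    return predict_ggia(dos, effects)


def _phenotype_gia(cohort: Cohort, probes: Cohort, spec: StageSpec,
                   rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """GIA entry mean: half the candidate's intercrop value, half the mean
    probe value, plus one error draw at the stage's fixed entry-mean
    error variance (anchored at the founder additive variance of 1, as
    the stage h^2 targets are defined). Returns (phenotypes, entry-mean
    error variance)."""
    v = stage_mean_error_variance(spec.h2)
    return (cohort.a_ic / 2.0 + probes.a_ic.mean() / 2.0
            + rng.normal(0.0, np.sqrt(v), size=len(cohort))), v


def _phenotype_pairs(pairs: PairSet, spec: StageSpec,
                     rng: np.random.Generator) -> float:
    """Intercrop combination plot entry means: the pair mean of the two
    members' intercrop values plus one error draw at the stage's fixed
    entry-mean error variance (founder-anchored). Returns the entry-mean
    error variance used."""
    g = 0.5 * (pairs.a_ic_A + pairs.a_ic_B)
    v = stage_mean_error_variance(spec.h2)
    pairs.pheno = g + rng.normal(0.0, np.sqrt(v), size=len(pairs))
    return v


def _record_pairs(state: PipelineState, pairs: PairSet, stage: str,
                  year: int, spec: StageSpec, resid_var: float) -> None:
    for k in range(len(pairs)):
        _record(state, year=year, stage=stage, trait="ic", crop=None,
                id_A=int(pairs.ids_A[k]), id_B=int(pairs.ids_B[k]),
                value=pairs.pheno[k], resid_var=resid_var, reps=spec.reps)


def _sia_pairs_from_lines(lines_A: Cohort, lines_B: Cohort) -> PairSet:
    """All pairwise intercrop combinations of the two crops' selected lines."""
    ia, ib = np.meshgrid(np.arange(len(lines_A)), np.arange(len(lines_B)), indexing="ij")
    ia, ib = ia.ravel(), ib.ravel()
    return PairSet(
        ids_A=lines_A.ids[ia], ids_B=lines_B.ids[ib],
        a_ic_A=lines_A.a_ic[ia], a_ic_B=lines_B.a_ic[ib],
    )


def _update_block_from_gia1(state: PipelineState, cs: CropState, cohort: Cohort,
                            scores: np.ndarray, year: int) -> None:
    """Stage the best n GIA1 genotypes as incoming parents and admit last
    year's staged selections to the block in place of its n longest-serving
    members. Parents are *selected* in the GIA1 year but only *enter* the
    crossing block the following year (seed increase), which sets the
    5-year generation interval of the GIA1-recycling programs. Genotypes
    currently serving as probe varieties are not eligible."""
    design = state.design
    if cs.incoming_parents is not None:
        newcomers = cs.incoming_parents
        newcomers.entry_year = np.full(len(newcomers), year, dtype=np.int32)
        block = cs.block
        oldest = np.lexsort((block.ids, block.entry_year))[:design.n_new_parents]
        kept = block.take(np.setdiff1d(np.arange(len(block)), oldest))
        cs.block = concat_cohorts(kept, newcomers)
    eligible = np.flatnonzero(~np.isin(cohort.ids, cs.probes.ids))
    chosen = eligible[_top_idx(scores[eligible], cohort.ids[eligible],
                               design.n_new_parents)]
    cs.incoming_parents = cohort.take(chosen)


def _make_crosses(state: PipelineState, cs: CropState, rng: np.random.Generator) -> None:
    design = state.design
    block = cs.block
    if design.crossing == "random":
        pairs = make_crosses_random(len(block), design.n_crosses, rng)
    else:
        try:
            pairs = make_crosses_max_avoidance(
                block.family, state.ma_generation, design.n_crosses)
        except ValueError:
            logger.warning("%s: family structure unusable, falling back to random crossing",
                           design.name)
            pairs = make_crosses_random(len(block), design.n_crosses, rng)
    cs.pending.append([
        (block.haplo[i, 0].copy(), block.haplo[j, 0].copy(),
         int(block.ids[i]), int(block.ids[j]))
        for i, j in pairs
    ])


def _grid_init_step(state: PipelineState, year: int, rng: np.random.Generator) -> None:
    """Grid-program initialization during the last burn-in years.

    The best ``init_keep`` PYT genotypes per crop are selected -- by
    monocrop phenotype in the first initialization year (no grid records
    exist yet), thereafter by gGIA from the grid model trained on the
    accumulated initialization records -- and all init_keep^2 intercrop
    combinations are field-tested at the grid stage's (reps, h^2). This
    seeds the training window the reorganized program needs in its first
    future year."""
    gdesign = state.grid_design
    first_year = state.burnin_years - gdesign.window_years + 1
    effects = _fit_grid_model(state, year) if year > first_year else None
    selected = {}
    for crop in CROPS:
        cs = state.crops[crop]
        cohort = cs.to_pyt
        if cohort is None or cohort.pheno is None:
            return
        scores = cohort.pheno if effects is None else _ggia(cs, cohort, effects)
        sel = cohort.take(_top_idx(scores, cohort.ids, gdesign.init_keep))
        _store_genotypes(state.grid_geno[crop], cs, sel, year, state.value_store[crop])
        selected[crop] = sel
    pairs = _sia_pairs_from_lines(selected["A"], selected["B"])
    v = _phenotype_pairs(pairs, gdesign.grid, rng)
    _record_pairs(state, pairs, "GRID", year, gdesign.grid, v)


# ---------------------------------------------------------------------------
# the year loop


def advance_year(state: PipelineState, rng: np.random.Generator) -> PipelineState:
    """Execute one calendar year of the current program design (in place)."""
    t = state.year + 1
    design = state.design
    in_burnin = t <= state.burnin_years
    gs = design.selection == "gs" and not in_burnin

    # 1. genomic model fits on the record window up to year t-1
    if gs:
        if design.kind == "grid":
            state.grid_effects = _fit_grid_model(state, t)
        else:
            _fit_conventional_models(state, t)

    # 2a. DH production and (conventional) DH phenotyping
    for crop in CROPS:
        cs = state.crops[crop]
        if not cs.pending:
            raise RuntimeError(f"pipeline integrity: no crosses pending in year {t}")
        cs.dh = _new_cohort_from_crosses(state, cs, t, design.total_dh, rng)
        if design.kind == "conventional":
            v = stage_mean_error_variance(design.dh_h2)
            cs.dh.pheno = cs.dh.a_m + rng.normal(0.0, np.sqrt(v), size=len(cs.dh))
        if gs:
            effects = state.grid_effects if design.kind == "grid" else cs.effects
            cs.dh.ggia = _ggia(cs, cs.dh, effects)

    # 2b. conventional monocrop and GIA stages
    if design.kind == "conventional":
        for crop in CROPS:
            cs = state.crops[crop]
            if cs.to_pyt is not None:
                cohort = cs.to_pyt
                v = stage_mean_error_variance(design.pyt.h2)
                cohort.pheno = cohort.a_m + rng.normal(0.0, np.sqrt(v), size=len(cohort))
                for i in range(len(cohort)):
                    _record(state, year=t, stage="PYT", trait="m", crop=crop,
                            id=int(cohort.ids[i]), value=cohort.pheno[i],
                            resid_var=v, reps=design.pyt.reps)
                _store_genotypes(state.conv_geno[crop], cs, cohort, t,
                                 state.value_store[crop])
                if gs:
                    cohort.ggia = _ggia(cs, cohort, cs.effects)
        for crop, other in (("A", "B"), ("B", "A")):
            cs, po = state.crops[crop], state.crops[other]
            if cs.to_gia1 is not None:
                cohort = cs.to_gia1
                cohort.pheno, v = _phenotype_gia(
                    cohort, po.probes.take(np.array([0])), design.gia1, rng)
                for i in range(len(cohort)):
                    _record(state, year=t, stage="GIA1", trait="ic", crop=crop,
                            id=int(cohort.ids[i]), value=cohort.pheno[i],
                            resid_var=v, reps=design.gia1.reps)
                if gs:
                    cohort.ggia = _ggia(cs, cohort, cs.effects)
            if cs.to_gia2 is not None:
                cohort = cs.to_gia2
                cohort.pheno, v = _phenotype_gia(
                    cohort, po.probes.take(np.arange(1, len(po.probes))),
                    design.gia2, rng)
                for i in range(len(cohort)):
                    _record(state, year=t, stage="GIA2", trait="ic", crop=crop,
                            id=int(cohort.ids[i]), value=cohort.pheno[i],
                            resid_var=v, reps=design.gia2.reps)

    # 2c. grid stage
    grid_advanced: PairSet | None = None
    if design.kind == "grid":
        keep = {}
        for crop in CROPS:
            cs = state.crops[crop]
            keep[crop] = cs.dh.take(_top_idx(cs.dh.ggia, cs.dh.ids, design.grid_keep))
            _store_genotypes(state.grid_geno[crop], cs, keep[crop], t,
                             state.value_store[crop])
        field_pairs, adv_pairs = grid_sample_and_select(
            keep["A"].ggia, keep["B"].ggia, keep["A"].ids, keep["B"].ids,
            design.grid.entries, design.grid_advance, rng,
        )
        fp = PairSet(
            ids_A=keep["A"].ids[field_pairs[:, 0]],
            ids_B=keep["B"].ids[field_pairs[:, 1]],
            a_ic_A=keep["A"].a_ic[field_pairs[:, 0]],
            a_ic_B=keep["B"].a_ic[field_pairs[:, 1]],
        )
        v = _phenotype_pairs(fp, design.grid, rng)
        _record_pairs(state, fp, "GRID", t, design.grid, v)
        grid_advanced = PairSet(
            ids_A=keep["A"].ids[adv_pairs[:, 0]],
            ids_B=keep["B"].ids[adv_pairs[:, 1]],
            a_ic_A=keep["A"].a_ic[adv_pairs[:, 0]],
            a_ic_B=keep["B"].a_ic[adv_pairs[:, 1]],
        )

    # 2d. shared SIA stages and release
    if state.sia1_pairs is not None:
        v = _phenotype_pairs(state.sia1_pairs, design.sia1, rng)
        _record_pairs(state, state.sia1_pairs, "SIA1", t, design.sia1, v)
    if state.sia2_pairs is not None:
        p = state.sia2_pairs
        v = _phenotype_pairs(p, design.sia2, rng)
        _record_pairs(state, p, "SIA2", t, design.sia2, v)
        best = int(np.lexsort((p.ids_B, p.ids_A, -p.pheno))[0])
        state.released.append({
            "year": t, "id_A": int(p.ids_A[best]), "id_B": int(p.ids_B[best]),
            "pheno": float(p.pheno[best]),
            "true_pair_value": float(0.5 * (p.a_ic_A[best] + p.a_ic_B[best])),
        })

    # 3a. grid initialization protocol during the last burn-in years
    if (in_burnin and state.grid_design is not None
            and t > state.burnin_years - state.grid_design.window_years):
        _grid_init_step(state, t, rng)

    # 3b. selections feeding next year's stages (downstream first, so each
    # cohort is consumed before its slot is overwritten)
    if state.sia1_pairs is not None:
        p = state.sia1_pairs
        k = min(design.sia2.entries, len(p))
        state.sia2_pairs = p.take(np.lexsort((p.ids_B, p.ids_A, -p.pheno))[:k])
    else:
        state.sia2_pairs = None

    if design.kind == "conventional":
        sia_lines = {}
        for crop in CROPS:
            cs = state.crops[crop]
            # GIA2 -> SIA lines and next year's probe varieties
            if cs.to_gia2 is not None:
                cohort = cs.to_gia2
                sia_lines[crop] = cohort.take(
                    _top_idx(cohort.pheno, cohort.ids, design.n_sia_lines))
                n_p = min(design.n_probes, len(cohort))
                cs.probes = cohort.take(_top_idx(cohort.pheno, cohort.ids, n_p))
            # GIA1 -> GIA2, and parents from GIA1 where applicable
            if cs.to_gia1 is not None:
                cohort = cs.to_gia1
                scores = cohort.ggia if gs else cohort.pheno
                cs.to_gia2 = cohort.take(
                    _top_idx(scores, cohort.ids, design.gia2.entries))
                if design.parent_stage == "GIA1":
                    _update_block_from_gia1(state, cs, cohort, scores, t)
            else:
                cs.to_gia2 = None
            # PYT -> GIA1, and parents from the PYT pool where applicable
            if cs.to_pyt is not None:
                cohort = cs.to_pyt
                scores = cohort.ggia if gs else cohort.pheno
                cs.to_gia1 = cohort.take(
                    _top_idx(scores, cohort.ids, design.gia1.entries))
                if gs and design.parent_stage == "PYT":
                    cs.block.ggia = _ggia(cs, cs.block, cs.effects)
                    pool = concat_cohorts(cohort, cs.block)
                    newb = pool.take(np.sort(_top_idx(pool.ggia, pool.ids,
                                                      design.block_size)))
                    newb.entry_year = np.full(len(newb), t, dtype=np.int32)
                    cs.block = newb
            else:
                cs.to_gia1 = None
            # DH -> PYT, and parents from DH where applicable
            if gs and design.parent_stage == "DH":
                idx = np.sort(_top_idx(cs.dh.ggia, cs.dh.ids, design.pyt.entries))
            else:
                idx = _select_dh_within_family(cs.dh, cs.dh.pheno, design.pyt.entries)
            cs.to_pyt = cs.dh.take(idx)
            if gs and design.parent_stage == "DH":
                newb = select_parents_truncation(
                    cs.dh, cs.dh.ggia, design.n_new_parents)
                newb.entry_year = np.full(len(newb), t, dtype=np.int32)
                cs.block = newb
        if "A" in sia_lines and "B" in sia_lines:
            state.sia1_pairs = _sia_pairs_from_lines(sia_lines["A"], sia_lines["B"])
        else:
            state.sia1_pairs = None
    else:
        state.sia1_pairs = grid_advanced
        for crop in CROPS:
            cs = state.crops[crop]
            newb = select_parents_truncation(
                cs.dh, cs.dh.ggia, design.n_new_parents)
            newb.entry_year = np.full(len(newb), t, dtype=np.int32)
            cs.block = newb
            cs.to_pyt = cs.to_gia1 = cs.to_gia2 = None

    # 4. new crosses from the updated blocks
    for crop in CROPS:
        _make_crosses(state, state.crops[crop], rng)
    if design.crossing == "max_avoidance":
        state.ma_generation += 1

    _append_metrics(state, t, gs)
    state.year = t
    return state


def _append_metrics(state: PipelineState, t: int, gs: bool) -> None:
    from .evaluation import prediction_accuracy

    dhs = {c: state.crops[c].dh for c in CROPS}
    mean_ic = 0.5 * (dhs["A"].a_ic.mean() + dhs["B"].a_ic.mean())
    var_ic = float(np.var(np.concatenate([dhs["A"].a_ic, dhs["B"].a_ic])))
    acc = {}
    for c in CROPS:
        d = dhs[c]
        pred = d.ggia if (gs and d.ggia is not None) else d.pheno
        acc[c] = prediction_accuracy(pred, d.a_ic) if pred is not None else np.nan
    state.metrics.append({
        "year": t, "program": state.design.name,
        "mean_ic": float(mean_ic), "var_ic": var_ic,
        "acc_A": acc["A"], "acc_B": acc["B"],
        "n_dh": len(dhs["A"]) + len(dhs["B"]),
    })


# ---------------------------------------------------------------------------
# drivers


def initialize_state(
    founders: dict[str, FounderSet],
    archs: dict[str, TraitArchitecture],
    burnin_design: ProgramDesign,
    grid_design: ProgramDesign | None,
    burnin_years: int,
    rng: np.random.Generator,
) -> PipelineState:
    """Set up year-0 state: founder crossing blocks, probe varieties, and
    the first round of crosses."""
    crops = {}
    for crop in CROPS:
        fs = founders[crop]
        arch = archs[crop]
        n = fs.n_founders
        a_m, a_ic = genetic_values(fs.dosages(fs.site_map.qtn_idx), arch)
        cohort = Cohort(
            ids=np.arange(n, dtype=np.int64),
            haplo=fs.diploid_haplotypes(),
            family=np.arange(n, dtype=np.int64) - n,  # unique pseudo-families
            a_m=a_m, a_ic=a_ic,
            birth_year=np.zeros(n, dtype=np.int32),
        )
        perm = rng.permutation(n)
        block_idx = np.sort(perm[:burnin_design.block_size])
        probe_pool = perm[burnin_design.block_size:]
        probe_idx = np.sort(probe_pool[:4] if probe_pool.size >= 4 else perm[:4])
        block = cohort.take(block_idx)
        block.entry_year = np.zeros(len(block), dtype=np.int32)
        crops[crop] = CropState(
            crop=crop, site_map=fs.site_map,
            qtn_idx=fs.site_map.qtn_idx, snp_idx=fs.site_map.snp_idx,
            arch=arch, block=block, probes=cohort.take(probe_idx),
            pending=[], next_id=n,
        )
    state = PipelineState(
        design=burnin_design, grid_design=grid_design,
        burnin_years=burnin_years, year=0, crops=crops,
    )
    for crop in CROPS:
        for g in range(founders[crop].n_founders):
            state.pedigree[crop][g] = (-1, -1, 0)
        # DH production takes two years, so two independent founder cross
        # rounds fill the queue and a DH cohort appears from year 1 onward
        _make_crosses(state, state.crops[crop], rng)
        _make_crosses(state, state.crops[crop], rng)
    return state


def run_burnin(state: PipelineState, rng: np.random.Generator) -> PipelineState:
    """Run the shared phenotypic-selection burn-in phase to completion."""
    while state.year < state.burnin_years:
        advance_year(state, rng)
    return state


def run_future(
    state: PipelineState,
    design: ProgramDesign,
    n_years: int,
    rng: np.random.Generator,
) -> PipelineState:
    """Run one future program arm from the end-of-burn-in state (in place)."""
    if state.year != state.burnin_years:
        raise ValueError("future phase must start exactly at the end of burn-in")
    state.design = design
    end = state.burnin_years + n_years
    while state.year < end:
        advance_year(state, rng)
    return state
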