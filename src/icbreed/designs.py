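"""Declarative descriptions of the five intercrop breeding program designs.

The five schemes compared are:

* **Pheno** -- phenotypic selection throughout (also the shared burn-in
  program): 100 crosses x 50 DH per crop, PYT, two general-intercropping-
  ability (GIA) stages with probe varieties, and two specific-
  intercropping-ability (SIA) stages shared between the crops.
* **Baseline-GS** -- genomic selection replaces phenotypic selection at
  the PYT and GIA1 stages; parents still come from GIA1 (generation
  interval 5 years).
* **PYT-GS** -- as Baseline-GS, but parents are the best 80 by gGIA out of
  the PYT cohort and last year's crossing block (generation interval 3).
* **DH-GS** -- genomic selection from the DH stage onward; parents are 80
  DH lines chosen by gGIA under a maximum-avoidance crossing scheme
  (generation interval 2).
* **Grid-GS** -- the monocrop and GIA stages are replaced by a 'grid'
  stage: the best 500 DH per crop by gGIA span 250,000 candidate pairs, of
  which 900 are field-tested and the 50 best-predicted advance to SIA1.

Stage sizes, replications, and entry-mean heritabilities follow the
medium-budget (~US$500K/year) parameterization; DH-per-cross numbers in
the genomic programs are budget-matched to the phenotypic program via
:func:`icbreed.costing.budget_scale`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "StageSpec",
    "ProgramDesign",
    "PROGRAM_NAMES",
    "medium_designs",
    "desk_designs",
]

PROGRAM_NAMES = ("Pheno", "Baseline-GS", "PYT-GS", "DH-GS", "Grid-GS")


@dataclass(frozen=True)
class StageSpec:
    """One testing stage: entries tested, effective reps, target h^2."""

    entries: int
    reps: int
    h2: float


@dataclass(frozen=True)
class ProgramDesign:
    """All parameters of one breeding scheme.

    ``kind`` is 'conventional' (Pheno and the three Conventional genomic
    programs, which share the PYT/GIA/SIA stage skeleton) or 'grid'.
    SIA-stage entries count intercrop *combinations*, which are shared
    between the two crops; all per-crop stages are run once per crop.
    """

    name: str
    kind: str                     # 'conventional' | 'grid'
    n_crosses: int
    dh_per_cross: int
    block_size: int
    genotyping: str               # 'none' | 'pyt' | 'all_dh'
    crossing: str                 # 'random' | 'max_avoidance'
    selection: str                # 'pheno' | 'gs'
    parent_stage: str             # 'GIA1' | 'PYT' | 'DH'
    n_new_parents: int
    dh_reps: int = 1
    dh_h2: float = 0.10
    n_probes: int = 4
    window_years: int = 5
    # conventional stages (per crop)
    pyt: StageSpec | None = None
    gia1: StageSpec | None = None
    gia2: StageSpec | None = None
    n_sia_lines: int = 3          # lines per crop advanced from GIA2 to SIA
    # SIA stages (combinations, shared)
    sia1: StageSpec | None = None
    sia2: StageSpec | None = None
    # grid program
    grid: StageSpec | None = None  # entries = field-tested pairs
    grid_keep: int = 0             # DH kept per crop by gGIA (spans the pair grid)
    grid_advance: int = 0          # best-predicted pairs advanced to SIA1
    init_keep: int = 0             # per-crop PYT selections in the initialization years

    @property
    def total_dh(self) -> int:
        """New DH lines per crop per year."""
        return self.n_crosses * self.dh_per_cross

    def with_dh_per_cross(self, n: int) -> "ProgramDesign":
        return replace(self, dh_per_cross=n)


def _pheno_medium() -> ProgramDesign:
    return ProgramDesign(
        name="Pheno", kind="conventional",
        n_crosses=100, dh_per_cross=50, block_size=80,
        genotyping="none", crossing="random", selection="pheno",
        parent_stage="GIA1", n_new_parents=20,
        pyt=StageSpec(500, 4, 0.33),
        gia1=StageSpec(50, 4, 0.33),
        gia2=StageSpec(13, 24, 0.50),
        n_sia_lines=3,
        sia1=StageSpec(9, 16, 0.67),
        sia2=StageSpec(3, 32, 0.80),
    )


def medium_designs() -> dict[str, ProgramDesign]:
    """The five full-scale medium-budget program designs."""
    pheno = _pheno_medium()
    baseline = replace(
        pheno, name="Baseline-GS", dh_per_cross=47,
        genotyping="pyt", selection="gs",
    )
    pyt_gs = replace(
        baseline, name="PYT-GS", parent_stage="PYT", n_new_parents=80,
    )
    dh_gs = replace(
        pheno, name="DH-GS", n_crosses=40, dh_per_cross=80,
        genotyping="all_dh", selection="gs", crossing="max_avoidance",
        parent_stage="DH", n_new_parents=80,
    )
    grid = ProgramDesign(
        name="Grid-GS", kind="grid",
        n_crosses=40, dh_per_cross=90, block_size=80,
        genotyping="all_dh", crossing="max_avoidance", selection="gs",
        parent_stage="DH", n_new_parents=80,
        grid=StageSpec(900, 1, 0.10), grid_keep=500, grid_advance=50,
        sia1=StageSpec(50, 16, 0.67),
        sia2=StageSpec(8, 32, 0.80),
        init_keep=23,
    )
    return {d.name: d for d in (pheno, baseline, pyt_gs, dh_gs, grid)}


def desk_designs() -> dict[str, ProgramDesign]:
    """Scaled-down ('desk') versions of the five designs.

    The phenotypic program is shrunk to 20 crosses x 25 DH per crop with
    downstream stages reduced roughly in proportion (PYT 100, GIA1 20,
    GIA2 8, SIA as at full scale); the genomic programs are then
    budget-matched to the desk phenotypic program's annual cost with the
    same lever as at full scale (the number of DH per cross). The
    maximum-avoidance arms keep their full-scale crossing structure (40
    crosses, 80 parents) and shrink only the family size through the
    budget lever (8 DH for DH-GS, 11 for Grid-GS): because their parents
    are DH lines and DH production takes two years, even- and odd-year
    cohorts form two closed lineages, so the number of parents per cycle
    -- not the family size -- is what keeps each lineage's genetic
    variance (and hence the arm's 20-year response) viable at small
    scale. The desk grid stage field-tests 360 of the 100 x 100
    candidate pairs per year: pair records are the grid model's only
    information source, and fewer desk plots leave that model too noisy
    to express the design contrast the grid program is built around.
    """
    from .costing import UnitCosts, annual_cost, budget_scale

    pheno = ProgramDesign(
        name="Pheno", kind="conventional",
        n_crosses=20, dh_per_cross=25, block_size=20,
        genotyping="none", crossing="random", selection="pheno",
        parent_stage="GIA1", n_new_parents=5,
        pyt=StageSpec(100, 4, 0.33),
        gia1=StageSpec(20, 4, 0.33),
        gia2=StageSpec(8, 24, 0.50),
        n_sia_lines=3,
        sia1=StageSpec(9, 16, 0.67),
        sia2=StageSpec(3, 32, 0.80),
    )
    costs = UnitCosts()
    target = annual_cost(pheno, costs).total
    baseline = replace(
        pheno, name="Baseline-GS", genotyping="pyt", selection="gs",
    )
    pyt_gs = replace(
        baseline, name="PYT-GS", parent_stage="PYT", n_new_parents=20,
    )
    dh_gs = replace(
        pheno, name="DH-GS", n_crosses=40, block_size=80,
        genotyping="all_dh", selection="gs", crossing="max_avoidance",
        parent_stage="DH", n_new_parents=80,
    )
    grid = ProgramDesign(
        name="Grid-GS", kind="grid",
        n_crosses=40, dh_per_cross=50, block_size=80,
        genotyping="all_dh", crossing="max_avoidance", selection="gs",
        parent_stage="DH", n_new_parents=80,
        grid=StageSpec(360, 1, 0.10), grid_keep=100, grid_advance=20,
        sia1=StageSpec(20, 16, 0.67),
        sia2=StageSpec(4, 32, 0.80),
        init_keep=10,
    )
    out = {"Pheno": pheno}
    for d in (baseline, pyt_gs, dh_gs, grid):
        out[d.name] = budget_scale(d, target, costs)
    return out


def get_designs(preset: str) -> dict[str, ProgramDesign]:
    if preset == "full":
        return medium_designs()
    if preset == "desk":
        return desk_designs()
    raise ValueError(f"unknown preset {preset!r}; expected 'full' or 'desk'")
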