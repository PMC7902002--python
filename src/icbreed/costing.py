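"""Annual operating cost of a breeding program design.

The accounting rule prices, per calendar year:

* DH production and PYT plots once per crop (x2);
* GIA plots once per crop (x2), since each crop's candidates are evaluated
  against the *other* crop's probe varieties;
* SIA and grid intercrop plots once (x1), since a specific combination is
  a single shared field plot;
* DH-stage single plants at no plot cost (seed increase, not a trial);
* genotyping for the 500 PYT entries per crop (Baseline-GS, PYT-GS), for
  every DH line per crop (DH-GS, Grid-GS), or not at all (Pheno).

With the unit costs below this reproduces the printed annual totals of all
five medium-budget designs exactly (493,200 / 492,200 / 492,200 / 495,200
/ 493,800 US$).
"""

from __future__ import annotations

from dataclasses import dataclass

from .designs import ProgramDesign

__all__ = ["UnitCosts", "CostBreakdown", "annual_cost", "budget_scale"]


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs in US$."""

    monocrop_plot: float = 20.0
    intercrop_plot: float = 50.0
    dh_line: float = 35.0
    genotyping: float = 20.0

    def __post_init__(self) -> None:
        for name in ("monocrop_plot", "intercrop_plot", "dh_line", "genotyping"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category annual dollars; total is their sum."""

    dh_production: float
    monocrop_plots: float
    intercrop_plots: float
    genotyping: float

    @property
    def total(self) -> float:
        return self.dh_production + self.monocrop_plots + self.intercrop_plots + self.genotyping


def _genotyped_samples(design: ProgramDesign) -> int:
    if design.genotyping == "none":
        return 0
    if design.genotyping == "pyt":
        if design.pyt is None:
            raise ValueError(f"{design.name}: PYT genotyping requires a PYT stage")
        return 2 * design.pyt.entries
    if design.genotyping == "all_dh":
        return 2 * design.total_dh
    raise ValueError(f"unknown genotyping policy {design.genotyping!r}")


def annual_cost(design: ProgramDesign, costs: UnitCosts | None = None) -> CostBreakdown:
    """Annual operating cost of one design under the accounting rule above."""
    costs = costs or UnitCosts()
    dh = 2 * design.total_dh * costs.dh_line
    if design.kind == "conventional":
        for stage in ("pyt", "gia1", "gia2", "sia1", "sia2"):
            if getattr(design, stage) is None:
                raise ValueError(f"{design.name}: missing stage parameters for {stage!r}")
        mono = 2 * design.pyt.entries * design.pyt.reps * costs.monocrop_plot
        inter = (
            2 * (design.gia1.entries * design.gia1.reps
                 + design.gia2.entries * design.gia2.reps)
            + design.sia1.entries * design.sia1.reps
            + design.sia2.entries * design.sia2.reps
        ) * costs.intercrop_plot
    elif design.kind == "grid":
        for stage in ("grid", "sia1", "sia2"):
            if getattr(design, stage) is None:
                raise ValueError(f"{design.name}: missing stage parameters for {stage!r}")
        mono = 0.0
        inter = (
            design.grid.entries * design.grid.reps
            + design.sia1.entries * design.sia1.reps
            + design.sia2.entries * design.sia2.reps
        ) * costs.intercrop_plot
    else:
        raise ValueError(f"unknown design kind {design.kind!r}")
    geno = _genotyped_samples(design) * costs.genotyping
    return CostBreakdown(
        dh_production=dh, monocrop_plots=mono, intercrop_plots=inter, genotyping=geno,
    )


def budget_scale(
    design: ProgramDesign,
    target_budget: float,
    costs: UnitCosts | None = None,
) -> ProgramDesign:
    """Adjust DH-per-cross so the design's annual cost meets a target budget.

    The number of doubled haploids per bi-parental cross is the lever used
    to equalize budgets across designs (it absorbs the genotyping cost of
    the genomic programs); downstream stage sizes are held fixed. The DH
    count is rounded to the nearest integer, so the re-priced total lands
    within one DH line's marginal cost of the target.
    """
    if target_budget <= 0:
        raise ValueError("target budget must be positive")
    costs = costs or UnitCosts()
    fixed = annual_cost(design.with_dh_per_cross(0), costs).total
    per_unit = annual_cost(design.with_dh_per_cross(1), costs).total - fixed
    n = int(round((target_budget - fixed) / per_unit))
    if n < 1:
        raise ValueError(
            f"{design.name}: budget {target_budget} infeasible; fixed downstream "
            f"costs are {fixed}"
        )
    return design.with_dh_per_cross(n)
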