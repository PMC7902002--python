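"""Replicated comparison experiments across the five breeding programs.

One *replicate* simulates a fresh founder population per crop, runs the
shared phenotypic-selection burn-in once, then branches every program arm
off a deep copy of the end-of-burn-in state. Arms within a replicate are
therefore seed-paired: they share founders, trait architecture, and
burn-in history, and differ only in the future phase. Gains are measured
relative to the end-of-burn-in mean intercrop genetic value of that
replicate, so gain ratios between arms cancel the common baseline.

All randomness descends from a single base seed through named
``numpy.random.SeedSequence`` spawn keys, so any (replicate, correlation,
arm) stream is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import PROGRAM_NAMES, get_designs
from .evaluation import RatioEstimate, gain_ratio
from .genome import FounderSet, GenomeParams, desk_genome_params, simulate_founders
from .programs import CROPS, initialize_state, run_burnin, run_future
from .traits import sample_architecture

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "compute_ratios"]

# spawn-key tags for the independent random streams
_KEY_FOUNDERS = 101
_KEY_ARCH = 102
_KEY_BURNIN = 103
_KEY_ARM0 = 104


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one replicated comparison experiment."""

    base_seed: int
    preset: str = "desk"                 # 'desk' | 'full'
    corrs: tuple = (0.9,)                # genetic correlations to sweep
    n_reps: int = 10
    n_founders: int = 100
    burnin_years: int = 20
    future_years: int = 20
    programs: tuple = PROGRAM_NAMES

    def __post_init__(self) -> None:
        if self.base_seed < 0:
            raise ValueError("base_seed must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(self.programs) - set(PROGRAM_NAMES)
        if unknown:
            raise ValueError(f"unknown programs: {sorted(unknown)}")
        if "Pheno" not in self.programs:
            raise ValueError("the Pheno arm is required as the comparison baseline")

    def genome_params(self) -> GenomeParams:
        return desk_genome_params() if self.preset == "desk" else GenomeParams()


def _rng(keys: list[int]) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(keys)))


def _corr_key(corr: float) -> int:
    return int(round(corr * 1000))


def _simulate_rep_founders(cfg: RunConfig, rep: int) -> dict[str, FounderSet]:
    params = cfg.genome_params()
    out = {}
    for ci, crop in enumerate(CROPS):
        seed_rng = _rng([cfg.base_seed, rep, _KEY_FOUNDERS, ci])
        out[crop] = simulate_founders(
            params, cfg.n_founders,
            seed=int(seed_rng.integers(1, 2**31 - 1)), crop_id=crop,
        )
    return out


def run_experiment(cfg: RunConfig) -> pd.DataFrame:
    """Run the full replicated comparison; returns tidy per-year metrics.

    Columns: rep, corr, program, phase ('burnin' once per (rep, corr),
    then one arm per program), year, gain (mean intercrop value centered
    at burn-in end), var_ic, acc_A, acc_B.
    """
    designs = get_designs(cfg.preset)
    grid_design = designs["Grid-GS"] if "Grid-GS" in cfg.programs else None
    rows = []
    for rep in range(cfg.n_reps):
        founders = _simulate_rep_founders(cfg, rep)
        for corr in cfg.corrs:
            ck = _corr_key(corr)
            archs = {
                crop: sample_architecture(
                    founders[crop], corr,
                    _rng([cfg.base_seed, rep, ck, _KEY_ARCH, ci]))
                for ci, crop in enumerate(CROPS)
            }
            burnin_rng = _rng([cfg.base_seed, rep, ck, _KEY_BURNIN])
            state = initialize_state(
                founders, archs, designs["Pheno"], grid_design,
                cfg.burnin_years, burnin_rng,
            )
            run_burnin(state, burnin_rng)
            baseline = state.metrics[-1]["mean_ic"]
            for m in state.metrics:
                rows.append({
                    "rep": rep, "corr": corr, "program": "Pheno",
                    "phase": "burnin", "year": m["year"],
                    "gain": m["mean_ic"] - baseline, "var_ic": m["var_ic"],
                    "acc_A": m["acc_A"], "acc_B": m["acc_B"],
                })
            for arm_idx, name in enumerate(cfg.programs):
                arm = state.snapshot()
                arm_rng = _rng([cfg.base_seed, rep, ck, _KEY_ARM0 + arm_idx])
                run_future(arm, designs[name], cfg.future_years, arm_rng)
                for m in arm.metrics:
                    if m["year"] <= cfg.burnin_years:
                        continue
                    rows.append({
                        "rep": rep, "corr": corr, "program": name,
                        "phase": "future", "year": m["year"],
                        "gain": m["mean_ic"] - baseline, "var_ic": m["var_ic"],
                        "acc_A": m["acc_A"], "acc_B": m["acc_B"],
                    })
            logger.info("rep %d corr %.2f done", rep, corr)
    return pd.DataFrame(rows)


def compute_ratios(metrics: pd.DataFrame, baseline: str = "Pheno") -> pd.DataFrame:
    """Endpoint gain ratio of every non-baseline arm over the baseline.

    The endpoint gain of an arm is the mean of its last *two* years' DH
    cohort gains. In the fast-cycling arms parents are DH lines and DH
    production takes two years, so even- and odd-year cohorts descend
    from disjoint parent sets; a single-year endpoint would score only
    one of the two and make the estimate a lottery on which one owns the
    final year. Averaging two adjacent years covers both (and is a
    negligible smoothing for the yearly-turnover arms). Gains are paired
    by replicate within each genetic correlation; the ratio is the
    geometric mean of the per-replicate ratios (see
    :func:`icbreed.evaluation.gain_ratio`). Replicates where either arm's
    endpoint gain is non-positive (possible in very short or tiny runs)
    cannot enter a log-ratio and are excluded with a logged count.
    """
    fut = metrics[metrics["phase"] == "future"]
    final_year = fut["year"].max()
    last = (
        fut[fut["year"] >= final_year - 1]
        .groupby(["corr", "program", "rep"], as_index=False)["gain"]
        .mean()
    )
    rows = []
    for corr, grp in last.groupby("corr", sort=True):
        base = grp[grp["program"] == baseline].set_index("rep")["gain"]
        for program in grp["program"].unique():
            if program == baseline:
                continue
            other = grp[grp["program"] == program].set_index("rep")["gain"]
            reps = base.index.intersection(other.index)
            x = other.loc[reps].to_numpy()
            y = base.loc[reps].to_numpy()
            keep = (x > 0) & (y > 0)
            if not keep.all():
                logger.warning(
                    "ratio %s/%s at corr %.2f: excluding %d of %d replicates "
                    "with non-positive endpoint gain",
                    program, baseline, corr, int((~keep).sum()), keep.size,
                )
                x, y = x[keep], y[keep]
            try:
                est = gain_ratio(x, y)
            except ValueError as exc:
                logger.warning("ratio %s/%s at corr %.2f unavailable: %s",
                               program, baseline, corr, exc)
                est = RatioEstimate(float("nan"), float("nan"), float("nan"),
                                    int(x.size))
            rows.append({
                "corr": corr, "program": program, "baseline": baseline,
                "year": final_year, "ratio": est.ratio,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "n_reps": est.n,
            })
    return pd.DataFrame(rows)
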