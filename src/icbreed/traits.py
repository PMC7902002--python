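"""Two-trait additive genetic architecture and stage-wise phenotypes.

Each crop carries two correlated traits: monocrop grain yield and intercrop
grain yield. Per-QTN additive effects for the pair of traits are sampled
from a bivariate standard normal with a chosen genetic correlation and then
rescaled so that the additive genetic variance of each trait equals 1 in
the founder population. Phenotypes add Gaussian noise whose variance is set
by the target entry-mean heritability of the breeding stage:

    h^2 = sigma2_A / (sigma2_A + sigma2_e / r)

with r the effective number of replications. Error variances are fixed
constants per stage, anchored at the founder additive variance of 1
(sigma2_e = r (1-h^2)/h^2): the target h^2 is a design property defined
against founder variance, so as selection erodes genetic variance the
realized heritability of later cohorts falls below the target -- the
plots do not get magically more precise as the material narrows.

Intercrop grain yield of a pair (i from crop A, j from crop B) is the mean
of the two genotypes' intercrop genetic values plus noise:

    y_ij = (a_ic_Ai + a_ic_Bj) / 2 + e_ij
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import FounderSet

__all__ = [
    "TraitArchitecture",
    "sample_architecture",
    "genetic_values",
    "error_variance_for_h2",
    "stage_mean_error_variance",
    "phenotype_monocrop",
    "phenotype_intercrop",
]


@dataclass
class TraitArchitecture:
    """Additive QTN effects of one crop for the (monocrop, intercrop) traits.

    ``alpha_m`` and ``alpha_ic`` are per-QTN effects on the dosage scale
    (0/2 copies for DH lines), rescaled so that the founder-population
    variance of each trait's genetic values is exactly 1.
    """

    qtn_idx: np.ndarray        # site indices of the QTN within the site map
    alpha_m: np.ndarray        # (n_qtn,)
    alpha_ic: np.ndarray       # (n_qtn,)
    target_correlation: float
    founder_variance: float = 1.0

    @property
    def n_qtn(self) -> int:
        return self.alpha_m.size


def sample_architecture(
    founders: FounderSet,
    target_correlation: float,
    rng: np.random.Generator,
) -> TraitArchitecture:
    """Draw and variance-scale the two-trait QTN effects for one crop.

    Effect pairs are drawn from a standard bivariate normal with the target
    correlation (via its Cholesky factor, so a target of exactly 1 yields
    identical effect vectors). Each trait's effects are then divided by the
    standard deviation of the founder genetic values, giving founder
    additive variance exactly 1 per trait. The realized founder genetic
    correlation fluctuates around the target with the finite number of QTN.
    """
    rho = float(target_correlation)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"target_correlation must lie in [-1, 1], got {rho}")
    qtn_idx = founders.site_map.qtn_idx
    nq = qtn_idx.size
    z = rng.standard_normal((nq, 2))
    alpha_m = z[:, 0]
    alpha_ic = rho * z[:, 0] + np.sqrt(max(1.0 - rho * rho, 0.0)) * z[:, 1]

    dos = founders.dosages(qtn_idx)
    for alpha in (alpha_m, alpha_ic):
        sd = np.std(dos @ alpha)  # population (divide-by-n) convention
        if sd == 0:
            raise ValueError(
                "founder genetic variance is zero; the founder set has no "
                "segregating QTN (did you pass a single founder?)"
            )
        alpha /= sd
    return TraitArchitecture(
        qtn_idx=qtn_idx, alpha_m=alpha_m, alpha_ic=alpha_ic,
        target_correlation=rho,
    )


def genetic_values(dosage: np.ndarray, arch: TraitArchitecture) -> tuple[np.ndarray, np.ndarray]:
    """True genetic values (a_m, a_ic) from QTN dosages.

    ``dosage`` has shape (..., n_qtn) on the 0/2 copy scale (DH lines) and
    is multiplied into the additive effects of both traits.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.shape[-1] != arch.n_qtn:
        raise ValueError(
            f"dosage has {dosage.shape[-1]} QTN but architecture has {arch.n_qtn}"
        )
    return dosage @ arch.alpha_m, dosage @ arch.alpha_ic


def error_variance_for_h2(h2: float, sigma2A: float = 1.0, r: float = 1.0) -> float:
    """Per-plot error variance implied by a target entry-mean heritability.

    Inverts h^2 = sigma2_A / (sigma2_A + sigma2_e / r) for sigma2_e.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"h2 must lie in (0, 1], got {h2}")
    if sigma2A <= 0:
        raise ValueError("sigma2A must be positive")
    if r < 1:
        raise ValueError("r must be >= 1")
    return r * sigma2A * (1.0 - h2) / h2


def stage_mean_error_variance(h2: float, sigma2A: float = 1.0) -> float:
    """Error variance of an entry-mean phenotype, sigma2_e / r = sigma2A (1-h2)/h2.

    Entry means over r replications are simulated with a single error draw
    at the rep-adjusted variance.
    """
    return error_variance_for_h2(h2, sigma2A, 1.0)


def phenotype_monocrop(
    a_m: np.ndarray | float,
    sigma2e: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monocrop yield phenotype: genetic value plus N(0, sigma2e) noise."""
    if sigma2e < 0:
        raise ValueError("error variance must be non-negative")
    a_m = np.asarray(a_m, dtype=float)
    return a_m + rng.normal(0.0, np.sqrt(sigma2e), size=a_m.shape)


def phenotype_intercrop(
    a_ic_A: np.ndarray | float,
    a_ic_B: np.ndarray | float,
    sigma2e: float,
    rng: np.random.Generator,
    crop_A: str = "A",
    crop_B: str = "B",
) -> np.ndarray:
    """Intercrop yield of pairs: mean of the two genetic values plus noise.

    The two values must come from the two different component crops; a pair
    within one crop is not an intercrop plot.
    """
    if crop_A == crop_B:
        raise ValueError(
            f"an intercrop pair needs one genotype from each crop, got two from {crop_A!r}"
        )
    if sigma2e < 0:
        raise ValueError("error variance must be non-negative")
    a = np.broadcast_arrays(np.asarray(a_ic_A, float), np.asarray(a_ic_B, float))
    mean = 0.5 * (a[0] + a[1])
    return mean + rng.normal(0.0, np.sqrt(sigma2e), size=mean.shape)
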