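"""Ridge-regression (RR-BLUP) genomic prediction of intercropping ability.

Two marker-effect models are used by the breeding programs:

* a **multi-trait model** fitted per crop, in which monocrop yield records
  (PYT stage) and general-intercropping-ability records (GIA stages) are
  analysed jointly, with a 2x2 additive (co)variance matrix G coupling the
  monocrop and intercrop marker effects; and
* a **grid model** fitted jointly for both crops, in which each intercrop
  yield record of a pair (i in A, j in B) loads the SNP dosages of both
  members and per-crop marker-effect vectors are estimated simultaneously.

Both are exact mixed-model-equation solves with fixed effects of year-stage
cells, heterogeneous residual variances (the stage error variance divided
by the stage's effective number of replications), and marker-effect prior
variances obtained by dividing the known additive (co)variances by
sum_k 2 p_k q_k of the training genotypes (the usual RR-BLUP/GBLUP
equivalence scaling).

Scale convention: an intercrop plot carries *half* of a candidate's
intercrop genetic value (the partner's half is absorbed by the year-stage
fixed effect, or loaded explicitly in the grid model). The one-half
coefficient is therefore placed in the model's design rows, keeping marker
effects -- and hence predicted general intercropping abilities (gGIA) --
on the genetic-value scale on which G is measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "GridTrainingSet",
    "VarianceComponents",
    "MarkerEffects",
    "GridMarkerEffects",
    "true_variance_components",
    "regularize_variance_components",
    "fit_multitrait_rrblup",
    "fit_grid_rrblup",
    "predict_ggia",
    "grid_pair_ggia",
    "pair_ggia_matrix",
]

#: record column order shared by the window builders and the model fits
RECORD_COLUMNS = ["year", "stage", "trait", "crop", "id", "id_A", "id_B", "value", "resid_var", "reps"]


def _check_window(years: np.ndarray) -> None:
    if years.size and years.max() - years.min() > 4:
        raise ValueError(
            f"training records span {years.min()}..{years.max()}, "
            "exceeding the 5-year sliding window"
        )


@dataclass
class TrainingSet:
    """Single-crop training data for the multi-trait model.

    ``records`` holds one row per phenotypic record with columns
    (year, stage, trait, id, value, resid_var); trait is 'm' for monocrop
    (PYT) records and 'ic' for general-intercropping-ability records
    (GIA1/GIA2 entry means).
    """

    crop: str
    geno_ids: np.ndarray         # (n_g,)
    dosage: np.ndarray           # (n_g, m) raw 0/2 dosages
    records: pd.DataFrame
    a_m: np.ndarray | None = None   # true genetic values of the genotypes
    a_ic: np.ndarray | None = None  # (simulation privilege, for known G)

    def __post_init__(self) -> None:
        _check_window(self.records["year"].to_numpy())
        known = set(self.geno_ids.tolist())
        missing = ~self.records["id"].isin(known)
        if missing.any():
            raise ValueError(
                f"{int(missing.sum())} records reference genotypes absent from the training set"
            )


@dataclass
class GridTrainingSet:
    """Pair-indexed training data for the grid model (both crops jointly)."""

    geno_ids: dict[str, np.ndarray]
    dosage: dict[str, np.ndarray]
    records: pd.DataFrame        # year, stage, id_A, id_B, value, resid_var
    a_ic: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        _check_window(self.records["year"].to_numpy())


@dataclass
class VarianceComponents:
    """Known additive (co)variance matrix G and marker prior bookkeeping.

    For the multi-trait model G is the 2x2 matrix of the (monocrop,
    intercrop) genetic variances and covariance; for the grid model it is
    diag(var_A_ic, var_B_ic) of the two crops' intercrop-trait variances.
    Per-record residual variances live on the training records themselves.
    """

    G: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if not np.allclose(G, G.T):
            raise ValueError("G must be symmetric")
        if np.linalg.eigvalsh(G).min() < -1e-10:
            raise ValueError("G must be positive semi-definite")
        self.G = G


def true_variance_components(a_m: np.ndarray, a_ic: np.ndarray) -> VarianceComponents:
    """G computed from the true genetic values of a reference population.

    Uses the population (divide-by-n) convention, matching the founder
    variance scaling, so the founder population yields diag(G) = (1, 1).
    """
    a_m = np.asarray(a_m, float)
    a_ic = np.asarray(a_ic, float)
    if a_m.size < 2:
        raise ValueError("need at least 2 individuals to estimate variance components")
    dm = a_m - a_m.mean()
    di = a_ic - a_ic.mean()
    n = a_m.size
    G = np.array([
        [dm @ dm, dm @ di],
        [dm @ di, di @ di],
    ]) / n
    return VarianceComponents(G=G)


def regularize_variance_components(
    vc: VarianceComponents,
    min_var: float = 1e-6,
    max_corr: float = 0.99,
) -> VarianceComponents:
    """Make a 2x2 G safely positive definite for the marker-effect prior.

    Long-running selection can (nearly) fix the training population, which
    drives a trait variance to ~0 or the realized trait correlation to
    +-1 and makes the known-G prior singular. Variances are floored at
    ``min_var`` and the correlation clipped to ``max_corr`` in magnitude;
    away from fixation this returns G unchanged.
    """
    G = vc.G.copy()
    if G.shape != (2, 2):
        raise ValueError("regularization is defined for 2x2 G matrices")
    v0, v1 = max(G[0, 0], min_var), max(G[1, 1], min_var)
    r = G[0, 1] / np.sqrt(v0 * v1)
    r = float(np.clip(r, -max_corr, max_corr))
    c = r * np.sqrt(v0 * v1)
    return VarianceComponents(G=np.array([[v0, c], [c, v1]]))


@dataclass
class MarkerEffects:
    """Marker effects of the multi-trait model, plus the dosage centering."""

    a_m: np.ndarray
    a_ic: np.ndarray
    center: np.ndarray          # training-column dosage means
    fixed: pd.Series            # year-stage cell means (diagnostic)

    @property
    def n_markers(self) -> int:
        return self.a_m.size


@dataclass
class GridMarkerEffects:
    """Per-crop marker effects of the grid model, plus dosage centerings."""

    a: dict[str, np.ndarray]
    center: dict[str, np.ndarray]
    fixed: pd.Series


def _marker_prior_scale(dosage: np.ndarray) -> float:
    """sum_k 2 p_k q_k over markers, p from the training genotypes.

    Returns 0 when the training genotypes are monomorphic at every marker
    (complete fixation); callers then fall back to a zero-effect model.
    """
    p = dosage.mean(axis=0) / 2.0
    return float(np.sum(2.0 * p * (1.0 - p)))


def _cells(records: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Fixed-effect design: one indicator column per (year, stage) cell.

    Cell-mean coding is used, which is always estimable (every cell that
    appears has at least one record), making confounded year/stage labels
    impossible by construction.
    """
    keys = list(zip(records["year"].to_numpy(), records["stage"].to_numpy()))
    levels = sorted(set(keys))
    lookup = {k: i for i, k in enumerate(levels)}
    X = np.zeros((len(keys), len(levels)))
    for row, k in enumerate(keys):
        X[row, lookup[k]] = 1.0
    return X, levels


def _solve_mme(X: np.ndarray, Z: np.ndarray, P: np.ndarray,
               y: np.ndarray, rinv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact solve of the mixed-model equations.

    X: (n, f) fixed design; Z: (n, q) random design; P: (q, q) prior
    precision of the random effects; rinv: (n,) inverse residual variances.
    Returns (b, a).
    """
    A = np.hstack([X, Z])
    C = (A * rinv[:, None]).T @ A
    q = P.shape[0]
    C[-q:, -q:] += P
    rhs = (A * rinv[:, None]).T @ y
    try:
        sol = scipy.linalg.solve(C, rhs, assume_a="pos")
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fallback
        sol, *_ = np.linalg.lstsq(C, rhs, rcond=None)
    f = X.shape[1]
    return sol[:f], sol[f:]


def fit_multitrait_rrblup(ts: TrainingSet, vc: VarianceComponents) -> MarkerEffects:
    """Fit the two-trait marker-effect model for one crop.

    Monocrop records load the (centered) SNP dosages into the monocrop
    effect block; intercrop records load half the dosages into the
    intercrop block (see the module docstring for the scale convention).
    The marker-effect prior is G / (sum_k 2 p_k q_k), coupled across the
    two traits per marker.
    """
    if len(ts.records) == 0:
        raise ValueError("training set has no records")
    dosage = np.asarray(ts.dosage, dtype=float)
    m = dosage.shape[1]
    if m == 0:
        raise ValueError("training set has no SNP markers")
    G = vc.G
    if G.shape != (2, 2):
        raise ValueError("multi-trait model requires a 2x2 G matrix")
    if np.linalg.eigvalsh(G).min() <= 0:
        raise ValueError("G must be positive definite to build the marker-effect prior")

    center = dosage.mean(axis=0)
    W = dosage - center
    c = _marker_prior_scale(dosage)
    if c == 0:
        logger.warning("training genotypes are monomorphic at every marker; "
                       "returning a zero-effect model")
        return MarkerEffects(
            a_m=np.zeros(m), a_ic=np.zeros(m), center=center,
            fixed=pd.Series(dtype=float),
        )
    Ginv_c = np.linalg.inv(G) * c           # precision of (a_m, a_ic) per marker

    rec = ts.records
    row_of = {int(g): i for i, g in enumerate(ts.geno_ids)}
    idx = rec["id"].map(row_of).to_numpy()
    is_m = (rec["trait"] == "m").to_numpy()

    Z = np.zeros((len(rec), 2 * m))
    Z[is_m, :m] = W[idx[is_m]]
    Z[~is_m, m:] = 0.5 * W[idx[~is_m]]

    X, levels = _cells(rec)
    P = np.kron(Ginv_c, np.eye(m))
    y = rec["value"].to_numpy(dtype=float)
    rinv = 1.0 / rec["resid_var"].to_numpy(dtype=float)
    b, a = _solve_mme(X, Z, P, y, rinv)
    fixed = pd.Series(b, index=pd.MultiIndex.from_tuples(levels, names=["year", "stage"]))
    return MarkerEffects(a_m=a[:m], a_ic=a[m:], center=center, fixed=fixed)


def fit_grid_rrblup(ts: GridTrainingSet, vc: VarianceComponents) -> GridMarkerEffects:
    """Fit the joint two-crop marker-effect model on pair-indexed records.

    Each record's design row loads one half of each member's centered SNP
    dosages into that crop's marker-effect block, so the per-crop effects
    stay on the genetic-value scale. Records whose members are not among
    the genotyped training individuals are excluded (with a logged count).
    """
    crops = sorted(ts.geno_ids)
    if len(crops) != 2:
        raise ValueError("grid model requires genotypes for exactly two crops")
    cA, cB = crops
    dosage = {c: np.asarray(ts.dosage[c], dtype=float) for c in crops}
    m = {c: dosage[c].shape[1] for c in crops}
    row_of = {c: {int(g): i for i, g in enumerate(ts.geno_ids[c])} for c in crops}

    rec = ts.records
    ok = rec["id_A"].isin(row_of[cA]) & rec["id_B"].isin(row_of[cB])
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("grid model: excluded %d records with ungenotyped pair members", n_drop)
        rec = rec.loc[ok]
    if len(rec) == 0:
        raise ValueError("grid training set has no usable records")

    G = vc.G
    if G.shape != (2, 2) or G[0, 0] <= 0 or G[1, 1] <= 0:
        raise ValueError("grid model requires positive per-crop intercrop variances on diag(G)")

    center = {c: dosage[c].mean(axis=0) for c in crops}
    scale = {c: _marker_prior_scale(dosage[c]) for c in crops}
    if min(scale.values()) == 0:
        logger.warning("grid training genotypes are monomorphic at every marker "
                       "for at least one crop; returning a zero-effect model")
        return GridMarkerEffects(
            a={c: np.zeros(m[c]) for c in crops}, center=center,
            fixed=pd.Series(dtype=float),
        )
    W = {c: dosage[c] - center[c] for c in crops}
    iA = rec["id_A"].map(row_of[cA]).to_numpy()
    iB = rec["id_B"].map(row_of[cB]).to_numpy()
    Z = np.hstack([0.5 * W[cA][iA], 0.5 * W[cB][iB]])

    prec = np.concatenate([
        np.full(m[cA], scale[cA] / G[0, 0]),
        np.full(m[cB], scale[cB] / G[1, 1]),
    ])
    X, levels = _cells(rec)
    y = rec["value"].to_numpy(dtype=float)
    rinv = 1.0 / rec["resid_var"].to_numpy(dtype=float)
    b, a = _solve_mme(X, Z, np.diag(prec), y, rinv)
    fixed = pd.Series(b, index=pd.MultiIndex.from_tuples(levels, names=["year", "stage"]))
    return GridMarkerEffects(
        a={cA: a[:m[cA]], cB: a[m[cA]:]},
        center=center,
        fixed=fixed,
    )


def predict_ggia(dosage: np.ndarray, effects: MarkerEffects | GridMarkerEffects,
                 crop: str | None = None) -> np.ndarray:
    """Genomic-predicted general intercropping ability of genotyped lines.

    gGIA is the centered SNP dosage times the intercrop marker effects.
    Any genotyped individual can be predicted, phenotyped or not. No
    intercept is added: every downstream use ranks candidates, so a
    constant shift is immaterial.
    """
    dosage = np.asarray(dosage, dtype=float)
    if isinstance(effects, GridMarkerEffects):
        if crop is None:
            raise ValueError("crop must be given when predicting from the grid model")
        a, center = effects.a[crop], effects.center[crop]
    else:
        a, center = effects.a_ic, effects.center
    if dosage.shape[-1] != a.size:
        raise ValueError(f"dosage has {dosage.shape[-1]} markers, effects have {a.size}")
    return (dosage - center) @ a


def grid_pair_ggia(ggia_A, ggia_B):
    """gGIA of an intercrop pair: the mean of the two members' gGIAs."""
    return 0.5 * (np.asarray(ggia_A, float) + np.asarray(ggia_B, float))


def pair_ggia_matrix(ggia_A: np.ndarray, ggia_B: np.ndarray) -> np.ndarray:
    """All pairwise pair-gGIAs as an (n_A, n_B) matrix."""
    return 0.5 * (np.asarray(ggia_A, float)[:, None] + np.asarray(ggia_B, float)[None, :])
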