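"""Genomic prediction models, checked against dense GLS oracles.

The RR-BLUP fits solve Henderson's mixed-model equations. The oracle here
takes the algebraically different marginal route: with marker prior
covariance P^-1 and residual covariance R, the GLS fixed effects are
b = (X' V^-1 X)^-1 X' V^-1 y with V = Z P^-1 Z' + R, and the marker BLUP
is a = P^-1 Z' V^-1 (y - X b). The two must agree to high precision on
small dense instances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icbreed.gsmodels import (
    GridTrainingSet,
    TrainingSet,
    VarianceComponents,
    fit_grid_rrblup,
    fit_multitrait_rrblup,
    grid_pair_ggia,
    pair_ggia_matrix,
    predict_ggia,
    regularize_variance_components,
    true_variance_components,
)


def _cell_design(records: pd.DataFrame) -> np.ndarray:
    keys = list(zip(records["year"].to_numpy(), records["stage"].to_numpy()))
    levels = sorted(set(keys))
    X = np.zeros((len(keys), len(levels)))
    for row, k in enumerate(keys):
        X[row, levels.index(k)] = 1.0
    return X


def _gls_oracle(X, Z, Pinv, y, resid_var):
    """Marginal-model GLS solution for (fixed effects, marker BLUP)."""
    V = Z @ Pinv @ Z.T + np.diag(resid_var)
    Vinv = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    a = Pinv @ Z.T @ Vinv @ (y - X @ b)
    return b, a


def _small_training_set(seed=0, n_geno=15, m=20):
    rng = np.random.default_rng(seed)
    ids = np.arange(100, 100 + n_geno, dtype=np.int64)
    dosage = 2.0 * rng.integers(0, 2, size=(n_geno, m)).astype(float)
    dosage[0] = 0.0
    dosage[1] = 2.0  # guarantee polymorphism overall but not per column
    rows = []
    for i, g in enumerate(ids):
        rows.append({"year": 10, "stage": "PYT", "trait": "m", "id": int(g),
                     "value": float(rng.normal()), "resid_var": 2.0 + i * 0.1})
    for g in ids[: n_geno // 2]:
        rows.append({"year": 11, "stage": "GIA1", "trait": "ic", "id": int(g),
                     "value": float(rng.normal()), "resid_var": 3.0})
    return TrainingSet(
        crop="A", geno_ids=ids, dosage=dosage, records=pd.DataFrame(rows),
    )


def test_multitrait_rrblup_matches_dense_gls_oracle():
    ts = _small_training_set()
    G = np.array([[1.0, 0.6], [0.6, 0.9]])
    effects = fit_multitrait_rrblup(ts, VarianceComponents(G=G))

    m = ts.dosage.shape[1]
    W = ts.dosage - ts.dosage.mean(axis=0)
    p = ts.dosage.mean(axis=0) / 2.0
    c = float(np.sum(2 * p * (1 - p)))
    row_of = {int(g): i for i, g in enumerate(ts.geno_ids)}
    idx = ts.records["id"].map(row_of).to_numpy()
    is_m = (ts.records["trait"] == "m").to_numpy()
    Z = np.zeros((len(ts.records), 2 * m))
    Z[is_m, :m] = W[idx[is_m]]
    Z[~is_m, m:] = 0.5 * W[idx[~is_m]]
    X = _cell_design(ts.records)
    Pinv = np.kron(G / c, np.eye(m))
    y = ts.records["value"].to_numpy(float)
    rv = ts.records["resid_var"].to_numpy(float)

    b, a = _gls_oracle(X, Z, Pinv, y, rv)
    np.testing.assert_allclose(effects.a_m, a[:m], atol=1e-8)
    np.testing.assert_allclose(effects.a_ic, a[m:], atol=1e-8)
    np.testing.assert_allclose(effects.fixed.to_numpy(), b, atol=1e-8)


def test_grid_rrblup_matches_dense_gls_oracle():
    rng = np.random.default_rng(3)
    nA, nB, m = 10, 12, 15
    ids = {"A": np.arange(nA, dtype=np.int64),
           "B": np.arange(50, 50 + nB, dtype=np.int64)}
    dosage = {c: 2.0 * rng.integers(0, 2, size=(n, m)).astype(float)
              for c, n in (("A", nA), ("B", nB))}
    rows = []
    for _ in range(40):
        ia, ib = rng.integers(nA), rng.integers(nB)
        rows.append({"year": 7, "stage": "GRID", "trait": "ic",
                     "id_A": int(ids["A"][ia]), "id_B": int(ids["B"][ib]),
                     "value": float(rng.normal()), "resid_var": 9.0})
    ts = GridTrainingSet(geno_ids=ids, dosage=dosage, records=pd.DataFrame(rows))
    G = np.diag([0.8, 1.2])
    effects = fit_grid_rrblup(ts, VarianceComponents(G=G))

    W = {c: dosage[c] - dosage[c].mean(axis=0) for c in ("A", "B")}
    scale = {c: float(np.sum(2 * (dosage[c].mean(0) / 2)
                             * (1 - dosage[c].mean(0) / 2))) for c in ("A", "B")}
    row_of = {c: {int(g): i for i, g in enumerate(ids[c])} for c in ("A", "B")}
    iA = ts.records["id_A"].map(row_of["A"]).to_numpy()
    iB = ts.records["id_B"].map(row_of["B"]).to_numpy()
    Z = np.hstack([0.5 * W["A"][iA], 0.5 * W["B"][iB]])
    X = _cell_design(ts.records)
    Pinv = np.diag(np.concatenate([
        np.full(m, G[0, 0] / scale["A"]), np.full(m, G[1, 1] / scale["B"]),
    ]))
    y = ts.records["value"].to_numpy(float)
    rv = ts.records["resid_var"].to_numpy(float)

    b, a = _gls_oracle(X, Z, Pinv, y, rv)
    np.testing.assert_allclose(effects.a["A"], a[:m], atol=1e-8)
    np.testing.assert_allclose(effects.a["B"], a[m:], atol=1e-8)
    np.testing.assert_allclose(effects.fixed.to_numpy(), b, atol=1e-8)


def test_training_window_span_enforced():
    ids = np.array([1, 2], dtype=np.int64)
    dosage = np.array([[0.0, 2.0], [2.0, 0.0]])
    rows = [
        {"year": 1, "stage": "PYT", "trait": "m", "id": 1, "value": 0.0, "resid_var": 1.0},
        {"year": 7, "stage": "PYT", "trait": "m", "id": 2, "value": 0.0, "resid_var": 1.0},
    ]
    with pytest.raises(ValueError, match="window"):
        TrainingSet(crop="A", geno_ids=ids, dosage=dosage, records=pd.DataFrame(rows))


def test_training_set_rejects_unknown_genotypes():
    ids = np.array([1], dtype=np.int64)
    dosage = np.array([[0.0, 2.0]])
    rows = [{"year": 1, "stage": "PYT", "trait": "m", "id": 99,
             "value": 0.0, "resid_var": 1.0}]
    with pytest.raises(ValueError, match="absent"):
        TrainingSet(crop="A", geno_ids=ids, dosage=dosage, records=pd.DataFrame(rows))


def test_true_variance_components_founder_oracle(founders_A, arch_A):
    from icbreed.traits import genetic_values

    a_m, a_ic = genetic_values(founders_A.dosages(arch_A.qtn_idx), arch_A)
    vc = true_variance_components(a_m, a_ic)
    assert vc.G[0, 0] == pytest.approx(1.0, abs=1e-10)
    assert vc.G[1, 1] == pytest.approx(1.0, abs=1e-10)
    assert vc.G[0, 1] == pytest.approx(np.cov(a_m, a_ic, bias=True)[0, 1], abs=1e-10)


def test_regularize_variance_components_floors_and_clips():
    vc = VarianceComponents(G=np.array([[0.0, 0.0], [0.0, 4.0]]))
    out = regularize_variance_components(vc)
    assert out.G[0, 0] == pytest.approx(1e-6)
    assert out.G[1, 1] == pytest.approx(4.0)
    # perfectly correlated traits get clipped to 0.99
    vc2 = VarianceComponents(G=np.array([[1.0, 1.0], [1.0, 1.0]]))
    out2 = regularize_variance_components(vc2)
    assert out2.G[0, 1] == pytest.approx(0.99)
    np.linalg.cholesky(out2.G)  # now positive definite
    # a healthy G passes through unchanged
    good = np.array([[1.0, 0.3], [0.3, 0.8]])
    np.testing.assert_allclose(regularize_variance_components(
        VarianceComponents(G=good)).G, good)


def test_monomorphic_training_gives_zero_effect_model():
    ids = np.array([1, 2], dtype=np.int64)
    dosage = np.full((2, 4), 2.0)
    rows = [{"year": 1, "stage": "PYT", "trait": "m", "id": int(g),
             "value": 0.5, "resid_var": 1.0} for g in ids]
    ts = TrainingSet(crop="A", geno_ids=ids, dosage=dosage, records=pd.DataFrame(rows))
    eff = fit_multitrait_rrblup(ts, VarianceComponents(G=np.eye(2)))
    assert np.all(eff.a_m == 0) and np.all(eff.a_ic == 0)


def test_predict_ggia_and_pair_helpers():
    ts = _small_training_set()
    eff = fit_multitrait_rrblup(ts, VarianceComponents(G=np.eye(2)))
    g = predict_ggia(ts.dosage, eff)
    np.testing.assert_allclose(g, (ts.dosage - eff.center) @ eff.a_ic)
    with pytest.raises(ValueError):
        predict_ggia(ts.dosage[:, :-1], eff)
    ga, gb = np.array([1.0, 3.0]), np.array([2.0])
    assert grid_pair_ggia(1.0, 3.0) == 2.0
    np.testing.assert_allclose(pair_ggia_matrix(ga, gb), [[1.5], [2.5]])


def test_grid_model_drops_ungenotyped_pairs(caplog):
    rng = np.random.default_rng(9)
    ids = {"A": np.arange(5, dtype=np.int64), "B": np.arange(10, 15, dtype=np.int64)}
    dosage = {c: 2.0 * rng.integers(0, 2, size=(5, 8)).astype(float) for c in ids}
    rows = [{"year": 3, "stage": "GRID", "trait": "ic", "id_A": 0, "id_B": 11,
             "value": 0.2, "resid_var": 9.0},
            {"year": 3, "stage": "GRID", "trait": "ic", "id_A": 999, "id_B": 11,
             "value": 0.1, "resid_var": 9.0}]
    ts = GridTrainingSet(geno_ids=ids, dosage=dosage, records=pd.DataFrame(rows))
    eff = fit_grid_rrblup(ts, VarianceComponents(G=np.eye(2)))
    assert eff.a["A"].shape == (8,)
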