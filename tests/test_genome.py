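"""Genome, meiosis, and doubled-haploid mechanics."""

from __future__ import annotations

import numpy as np
import pytest

from icbreed.genome import (
    FounderSet,
    GenomeParams,
    cross_dh,
    derive_recombination_rate,
    format_rate_2sf,
    gametes,
    make_dh,
    make_dh_batch,
    meiosis,
    simulate_founders,
)


def test_recombination_rate_is_exact_ratio():
    # 1.43 Morgans over 8e8 bp: 1.43 / 8e8 = 1.7875e-9 exactly.
    assert derive_recombination_rate(1.43, 8e8) == 1.43 / 8e8
    assert derive_recombination_rate(1.43, 8e8) == pytest.approx(1.7875e-9, rel=0, abs=1e-22)
    assert GenomeParams().recombination_rate == 1.43 / 8e8


def test_recombination_rate_two_significant_figures():
    assert format_rate_2sf(1.43 / 8e8) == "1.8e-09"
    assert format_rate_2sf(1.7875e-9) == "1.8e-09"


def test_recombination_rate_validates_lengths():
    with pytest.raises(ValueError):
        derive_recombination_rate(0.0, 8e8)
    with pytest.raises(ValueError):
        derive_recombination_rate(1.43, -1.0)


def test_desk_founders_shapes_and_roles(desk_params, founders_A):
    n_keep = desk_params.n_chromosomes * (
        desk_params.n_qtn_per_chr + desk_params.n_snp_per_chr
    )
    assert founders_A.haplotypes.shape == (40, n_keep)
    sm = founders_A.site_map
    assert sm.qtn_idx.size == desk_params.n_chromosomes * desk_params.n_qtn_per_chr
    assert sm.snp_idx.size == desk_params.n_chromosomes * desk_params.n_snp_per_chr
    # QTN and SNP roles partition the sites
    assert np.intersect1d(sm.qtn_idx, sm.snp_idx).size == 0
    # every kept site segregates among the founders
    dos = founders_A.dosages()
    assert (dos.min(axis=0) == 0).all() and (dos.max(axis=0) == 2).all()


def test_founders_deterministic(desk_params):
    a = simulate_founders(desk_params, 12, seed=99)
    b = simulate_founders(desk_params, 12, seed=99)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert np.array_equal(a.site_map.pos_bp, b.site_map.pos_bp)
    assert np.array_equal(a.site_map.is_qtn, b.site_map.is_qtn)


def test_founder_save_load_roundtrip(tmp_path, founders_A):
    path = tmp_path / "founders.npz"
    founders_A.save(str(path))
    loaded = FounderSet.load(str(path))
    assert loaded.crop_id == founders_A.crop_id
    assert np.array_equal(loaded.haplotypes, founders_A.haplotypes)
    assert np.array_equal(loaded.site_map.pos_morgan, founders_A.site_map.pos_morgan)


def test_gametes_alleles_come_from_parent(founders_A):
    rng = np.random.default_rng(0)
    parent = founders_A.diploid_haplotypes()[0]  # (2, L)
    # make the parent heterozygous by mixing two founders
    parent = np.stack([founders_A.haplotypes[0], founders_A.haplotypes[1]])
    g = gametes(parent, founders_A.site_map, rng, n=8)
    assert g.shape == (8, founders_A.site_map.n_sites)
    ok = (g == parent[0][None, :]) | (g == parent[1][None, :])
    assert ok.all()


def test_gametes_recombine(founders_A):
    # with 1.43 M per chromosome, gametes are essentially never a pure
    # parental haplotype at every one of the polymorphic sites
    rng = np.random.default_rng(1)
    parent = np.stack([founders_A.haplotypes[2], founders_A.haplotypes[3]])
    g = gametes(parent, founders_A.site_map, rng, n=50)
    pure = np.array([
        np.array_equal(x, parent[0]) or np.array_equal(x, parent[1]) for x in g
    ])
    assert pure.sum() < 50


def test_gametes_validates_parent_shape(founders_A):
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        gametes(founders_A.haplotypes[0], founders_A.site_map, rng)


def test_dh_is_fully_homozygous(founders_A):
    rng = np.random.default_rng(2)
    f1 = cross_dh(
        np.stack([founders_A.haplotypes[0]] * 2),
        np.stack([founders_A.haplotypes[1]] * 2),
    )
    dh = make_dh(f1, founders_A.site_map, rng)
    assert np.array_equal(dh[0], dh[1])
    batch = make_dh_batch(f1, founders_A.site_map, rng, n=20)
    assert batch.shape == (20, 2, founders_A.site_map.n_sites)
    assert np.array_equal(batch[:, 0, :], batch[:, 1, :])


def test_cross_dh_requires_homozygous_parents(founders_A):
    het = np.stack([founders_A.haplotypes[0], founders_A.haplotypes[1]])
    hom = np.stack([founders_A.haplotypes[2]] * 2)
    with pytest.raises(ValueError):
        cross_dh(het, hom)


def test_meiosis_single_gamete(founders_A):
    rng = np.random.default_rng(3)
    parent = np.stack([founders_A.haplotypes[0], founders_A.haplotypes[1]])
    g = meiosis(parent, founders_A.site_map, rng)
    assert g.shape == (founders_A.site_map.n_sites,)
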