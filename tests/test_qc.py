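"""Tests for quality control and trait construction."""

import numpy as np
import pandas as pd
import pytest

from matealloc.genotypes import GenotypeMatrix, PedigreeTable
from matealloc.qc import (
    RawPerformanceRecord,
    adjust_age,
    adjust_bd,
    compute_apwl,
    filter_animals,
    filter_snps,
    hwe_pvalue,
    intersect_panels,
    mendelian_check,
    run_qc,
)
from matealloc.simdata import make_qc_fixture


def _hwe_clean_block(n: int, m: int) -> np.ndarray:
    """Exact-HWE columns at p=0.5 for a divisible-by-4 n."""
    assert n % 4 == 0
    col = np.array([2.0] * (n // 4) + [1.0] * (n // 2) + [0.0] * (n // 4))
    return np.tile(col[:, None], (1, m))


def test_snp_retained_near_hwe_high_maf():
    # 100 animals, 1 missing call (call rate 0.99), counts AA=25, Aa=50, aa=24
    col = np.array([2.0] * 25 + [1.0] * 50 + [0.0] * 24 + [np.nan])
    counts = np.column_stack([_hwe_clean_block(100, 1)[:, 0], col])
    g = GenotypeMatrix(counts, [f"a{i}" for i in range(100)], ["clean", "test"])
    filtered, rep = filter_snps(g)
    assert "test" in filtered.snp_ids
    assert rep.n_snps_out == 2


def test_snp_removed_by_hwe_hand_chisquare():
    # AA=50, Aa=0, aa=50: expected (25,50,25), chi-square = 25+50+25 = 100
    col = np.array([2.0] * 50 + [0.0] * 50)
    counts = np.column_stack([_hwe_clean_block(100, 1)[:, 0], col])
    g = GenotypeMatrix(counts, [f"a{i}" for i in range(100)], ["clean", "bad"])
    filtered, rep = filter_snps(g)
    assert rep.snps_removed_hwe == ["bad"]
    assert hwe_pvalue(50, 0, 50) < 1e-20


def test_snp_removed_by_maf():
    # p = 0.04 via 8 het carriers among 100 animals
    col = np.array([1.0] * 8 + [0.0] * 92)
    counts = np.column_stack([_hwe_clean_block(100, 1)[:, 0], col])
    g = GenotypeMatrix(counts, [f"a{i}" for i in range(100)], ["clean", "rare"])
    filtered, rep = filter_snps(g)
    assert rep.snps_removed_maf == ["rare"]


def test_animal_callrate_filter():
    counts = _hwe_clean_block(100, 100)
    counts[0, :3] = np.nan  # 3% missing -> below 0.98
    g = GenotypeMatrix(counts, [f"a{i}" for i in range(100)], [f"s{j}" for j in range(100)])
    filtered = filter_animals(g)
    assert "a0" not in filtered.animal_ids
    assert filtered.n_animals == 99


def test_mendelian_single_conflict_rate_zero():
    counts = np.ones((2, 1000))
    counts[0, :] = 2.0  # parent AA everywhere
    counts[1, :] = 1.0  # offspring Aa everywhere
    counts[1, 0] = 0.0  # one opposite homozygote
    g = GenotypeMatrix(counts, ["p1", "k1"], [f"s{j}" for j in range(1000)])
    ped = PedigreeTable(pd.DataFrame({"animal": ["k1"], "sire": ["p1"], "dam": ["0"]}))
    assert mendelian_check(g, ped, conflict_rate_max=0.0) == ["k1"]
    # all-heterozygous offspring of an AA parent is never a conflict
    counts[1, 0] = 1.0
    g2 = GenotypeMatrix(counts, ["p1", "k1"], [f"s{j}" for j in range(1000)])
    assert mendelian_check(g2, ped, conflict_rate_max=0.0) == []


def test_mendelian_conflict_count_enumeration():
    k = 17
    m = 500
    counts = np.full((3, m), 2.0)
    counts[2, :] = 1.0
    counts[2, :k] = 0.0  # offspring aa at k loci of AA x AA parents
    g = GenotypeMatrix(counts, ["s", "d", "kid"], [f"s{j}" for j in range(m)])
    ped = PedigreeTable(pd.DataFrame({"animal": ["kid"], "sire": ["s"], "dam": ["d"]}))
    # flagged exactly when rate threshold is below k/m
    assert mendelian_check(g, ped, conflict_rate_max=(k - 1) / m) == ["kid"]
    assert mendelian_check(g, ped, conflict_rate_max=k / m) == []


def test_planted_fixture_recovered_exactly():
    geno, ped, planted = make_qc_fixture(seed=7)
    filtered, rep = run_qc(geno, ped)
    assert set(rep.snps_removed_callrate) == set(planted["callrate_snps"])
    assert set(rep.snps_removed_maf) == set(planted["maf_snps"])
    assert set(rep.snps_removed_hwe) == set(planted["hwe_snps"])
    assert set(rep.animals_removed_callrate) == set(planted["callrate_animals"])
    assert set(rep.animals_removed_mendelian) == set(planted["mendel_offspring"])
    assert filtered.n_snps == rep.n_snps_out


def test_intersect_panels():
    c1 = _hwe_clean_block(4, 3)
    c2 = _hwe_clean_block(4, 3)
    g1 = GenotypeMatrix(c1, ["a1", "a2", "a3", "a4"], ["s1", "s2", "s3"])
    g2 = GenotypeMatrix(c2, ["b1", "b2", "b3", "b4"], ["s2", "s3", "s4"])
    merged = intersect_panels(g1, g2)
    assert merged.snp_ids == ["s2", "s3"]
    assert merged.n_animals == 8
    g3 = GenotypeMatrix(c2, ["b1", "b2", "b3", "b4"], ["x1", "x2", "x3"])
    with pytest.raises(ValueError):
        intersect_panels(g1, g3)
    same = intersect_panels(g1, GenotypeMatrix(c2, ["c1", "c2", "c3", "c4"], ["s1", "s2", "s3"]))
    assert same.snp_ids == ["s1", "s2", "s3"]


def test_adjust_age_hand_values():
    base = dict(age_test=150.0, w_test=90.0, w_batch=100.0, age_batch=150.0)
    male = RawPerformanceRecord("m1", "male", **base)
    female = RawPerformanceRecord("f1", "female", **base)
    assert adjust_age(male) == pytest.approx(159.85, abs=1e-10)
    assert adjust_age(female) == pytest.approx(160.60, abs=1e-10)
    # zero adjustment at w_test = 100
    at100 = RawPerformanceRecord("m2", "male", age_test=150.0, w_test=100.0,
                                 w_batch=100.0, age_batch=150.0)
    assert adjust_age(at100) == pytest.approx(150.0)


def test_adjust_bd_hand_values():
    rec = RawPerformanceRecord("m1", "male", w_test=90.0, bd_six_site=(11.0,) * 6)
    assert adjust_bd(rec) == pytest.approx(12.0, abs=1e-12)
    at100 = RawPerformanceRecord("m2", "male", w_test=100.0, bd_six_site=(11.2,) * 6)
    assert adjust_bd(at100) == pytest.approx(11.2)


def test_apwl():
    assert compute_apwl((1200.0, 1400.0)) == pytest.approx(1300.0)
    with pytest.raises(ValueError):
        compute_apwl(())
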