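"""Simulator: crossing plans, meiosis, inbreeding, genotypes, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mppqtl.genmap import uniform_map
from mppqtl.simulate import (
    CrossingPlan,
    DesignError,
    Family,
    advance_population,
    assign_qtl_architecture,
    default_architecture,
    default_map,
    default_plan,
    expected_qtl_variance,
    make_crossing_plan,
    minor_qtl_positions,
    realize_genotypes,
    simulate_meiosis,
    simulate_phenotype,
    synthetic_founders,
)


# ---------------------------------------------------------------------------
# crossing plans
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "design, n_founders, size, kw, n_families, n_total",
    [
        ("diallel", 4, 50, {}, 6, 300),
        ("nam", 4, 100, {"central_founder": 0}, 3, 300),
        ("magic", 4, 300, {}, 1, 300),
        ("diallel", 2, 50, {}, 1, 50),  # degenerates to biparental
    ],
)
def test_crossing_plan_cardinalities(design, n_founders, size, kw, n_families, n_total):
    plan = make_crossing_plan(design, n_founders, size, 6, **kw)
    assert plan.n_families == n_families
    assert plan.n_individuals == n_total
    assert sum(f.size for f in plan.families) == n_total


def test_diallel_families_enumerate_pairs_lexicographically():
    plan = make_crossing_plan("diallel", 4, 10, 6)
    assert [f.parents for f in plan.families] == [
        (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)
    ]


def test_unsupported_designs_raise():
    with pytest.raises(DesignError):
        make_crossing_plan("magic", 3, 100, 6)  # not a power of 2
    with pytest.raises(DesignError):
        make_crossing_plan("nam", 4, 100, 6)  # no central founder
    with pytest.raises(DesignError):
        make_crossing_plan("backcross", 4, 100, 6)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _hap(bounds, origins):
    return np.asarray(bounds, float), np.asarray(origins, np.int64)


def test_crossover_counts_are_poisson_with_morgan_mean():
    rng = np.random.default_rng(7)
    pair = (_hap([100.0], [0]), _hap([100.0], [1]))
    counts = []
    for _ in range(10_000):
        bounds, origins = simulate_meiosis(pair, 100.0, rng)
        counts.append(len(origins) - 1)
    counts = np.asarray(counts)
    # mean junction count ~ mean crossovers (junctions <= crossovers only
    # through coincident switches, negligible here); 3 SE band around 1.0
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - 1.0) <= 3 * se
    # chi-square goodness of fit against Poisson(1)
    kmax = 6
    observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    expected = stats.poisson.pmf(np.arange(kmax + 1), 1.0)
    expected[kmax] = 1.0 - expected[:kmax].sum()
    chi2 = float(((observed - len(counts) * expected) ** 2 / (len(counts) * expected)).sum())
    assert stats.chi2.sf(chi2, kmax) > 0.01


def test_zero_length_chromosome_never_recombines():
    rng = np.random.default_rng(0)
    pair = (_hap([0.0], [0]), (np.array([0.0]), np.array([1])))
    for _ in range(50):
        bounds, origins = simulate_meiosis(pair, 0.0, rng)
        assert len(origins) == 1


def test_homozygous_parent_transmits_itself():
    rng = np.random.default_rng(1)
    hap = _hap([30.0, 100.0], [2, 0])
    for _ in range(50):
        bounds, origins = simulate_meiosis((hap, hap), 100.0, rng)
        assert np.array_equal(bounds, hap[0]) and np.array_equal(origins, hap[1])


# ---------------------------------------------------------------------------
# inbreeding by single seed descent
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("generation, expected_het", [(2, 0.5), (4, 0.125), (6, 0.03125)])
def test_heterozygosity_halves_per_selfing_generation(generation, expected_het):
    gmap = uniform_map({"1": 87.0})
    founders = np.vstack([np.ones(88, int), np.full(88, 2, int)])  # all loci segregate
    plan = make_crossing_plan("diallel", 2, 250, generation)
    mosaics = advance_population(plan, gmap, np.random.default_rng(generation))
    table = realize_genotypes(mosaics, founders, gmap, 0.0)
    # loci within an individual are linked; per-individual means are i.i.d.
    per_ind = (table.dosages == 1).mean(axis=1)
    se = per_ind.std(ddof=1) / np.sqrt(len(per_ind))
    assert abs(per_ind.mean() - expected_het) <= 3 * se


def test_identical_founders_give_identical_offspring():
    gmap = uniform_map({"1": 50.0}, 5.0)
    founders = np.vstack([np.ones(11, int), np.ones(11, int)])
    plan = make_crossing_plan("diallel", 2, 20, 6)
    mosaics = advance_population(plan, gmap, np.random.default_rng(3))
    table = realize_genotypes(mosaics, founders, gmap, 0.0)
    assert np.all(table.dosages == 0.0)  # everyone is homozygous allele 1


def test_magic_founder_contributions_are_uniform():
    gmap = uniform_map({"1": 99.0})
    plan = make_crossing_plan("magic", 4, 1000, 6)
    mosaics = advance_population(plan, gmap, np.random.default_rng(11))
    per_ind = np.empty((len(mosaics), 4))
    for i, m in enumerate(mosaics):
        orig = m.origins_at(gmap)
        per_ind[i] = [(orig == j).mean() for j in range(4)]
    shares = per_ind.mean(axis=0)
    se = per_ind.std(axis=0, ddof=1) / np.sqrt(len(mosaics))
    assert np.all(np.abs(shares - 0.25) <= 3 * se)


# ---------------------------------------------------------------------------
# observed genotypes
# ---------------------------------------------------------------------------


def test_realized_genotypes_missingness(study_map):
    rng = np.random.default_rng(5)
    founders = synthetic_founders(study_map, 4, rng)
    plan = default_plan("magic")
    mosaics = advance_population(plan, study_map, rng)

    exact = realize_genotypes(mosaics, founders, study_map, 0.0)
    assert not np.isnan(exact.dosages).any()

    masked = realize_genotypes(mosaics, founders, study_map, 0.05, rng)
    n = masked.dosages.size
    tol = 3 * np.sqrt(0.05 * 0.95 / n)
    assert abs(masked.missing_fraction - 0.05) <= tol
    # observed entries equal the truth
    obs = ~np.isnan(masked.dosages)
    assert np.array_equal(masked.dosages[obs], exact.dosages[obs])

    gone = realize_genotypes(mosaics[:5], founders, study_map, 1.0, rng)
    assert np.isnan(gone.dosages).all()


# ---------------------------------------------------------------------------
# QTL architecture
# ---------------------------------------------------------------------------


def test_minor_placement_rule_on_centred_major():
    assert minor_qtl_positions(50.0, 100.0) == [0.0, 10.0, 20.0, 30.0, 70.0, 80.0, 90.0, 100.0]


def test_default_architecture_counts(study_map):
    founders = synthetic_founders(study_map, 4, np.random.default_rng(0))
    arch = default_architecture(study_map, founders)
    assert len(arch.majors) == 3
    assert list(arch.majors["chrom"]) == ["1", "2", "3"]
    assert len(arch.minors) == 24
    assert arch.null_chrom == "5"
    assert not (arch.minors["chrom"] == "5").any()
    counts = arch.minors.groupby("chrom").size().to_dict()
    assert counts == {"1": 6, "2": 6, "3": 6, "4": 6}


def test_major_off_marker_or_shared_chromosome_rejected(study_map):
    founders = synthetic_founders(study_map, 4, np.random.default_rng(0))
    from mppqtl.genmap import MapError

    with pytest.raises(MapError):
        assign_qtl_architecture(study_map, founders, ["not_a_marker"])
    with pytest.raises(ValueError):
        assign_qtl_architecture(study_map, founders, ["m1_40", "m1_50"])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _monomorphic_population(study_map, allele):
    """Offspring identical to a founder homozygous for one allele everywhere."""
    founders = np.full((4, study_map.n_markers), allele, int)
    plan = make_crossing_plan("magic", 4, 3, 6)
    return advance_population(plan, study_map, np.random.default_rng(1)), founders


def test_phenotype_extremes_sum_all_effects(study_map):
    probe = synthetic_founders(study_map, 4, np.random.default_rng(0))
    arch = default_architecture(study_map, probe)
    for allele, sign in ((1, 1.0), (2, -1.0)):
        mosaics, founders = _monomorphic_population(study_map, allele)
        trait = simulate_phenotype(
            mosaics, founders, arch, study_map, residuals=np.zeros(len(mosaics))
        )
        expected = sign * (3 * 0.4 + 24 * 0.1)
        assert np.allclose(trait.y, expected)


def test_pure_noise_phenotype_has_unit_variance(study_map):
    probe = synthetic_founders(study_map, 4, np.random.default_rng(2))
    arch = default_architecture(study_map, probe)
    mosaics, founders = _monomorphic_population(study_map, 1)
    mosaics = mosaics * 3334  # reuse genomes; only the residuals matter at a=b=0
    rng = np.random.default_rng(3)
    trait = simulate_phenotype(
        mosaics, founders, arch, study_map, major_effect=0.0, minor_effect=0.0, rng=rng
    )
    assert len(trait.y) >= 10_000
    assert abs(np.var(trait.y) - 1.0) < 0.05


def test_phenotype_mean_centred_for_symmetric_configurations():
    gmap = uniform_map({"1": 80.0, "2": 80.0}, 1.0)
    rng = np.random.default_rng(8)
    founders = synthetic_founders(gmap, 4, rng)
    # symmetric carrier pattern: two founders carry each allele at the major
    j = gmap.marker_index("m1_40")
    founders[:, j] = [1, 1, 2, 2]
    arch = assign_qtl_architecture(gmap, founders, ["m1_40"], null_chrom="2")
    arch = arch.__class__(
        arch.majors, arch.minors.iloc[0:0], arch.founder_alleles, arch.null_chrom
    )  # majors only: minors have asymmetric random configurations
    plan = make_crossing_plan("magic", 4, 1200, 6)
    mosaics = advance_population(plan, gmap, rng)
    trait = simulate_phenotype(mosaics, founders, arch, gmap, rng=rng)
    se = np.std(trait.y) / np.sqrt(len(trait.y))
    assert abs(np.mean(trait.y)) <= 3.5 * se


# ---------------------------------------------------------------------------
# expected QTL variance
# ---------------------------------------------------------------------------


def test_expected_variance_magic_half_frequency():
    plan = make_crossing_plan("magic", 4, 300, 6)
    var, _ = expected_qtl_variance(plan, np.array([1, 1, 2, 2]), 0.4)
    assert var == pytest.approx(0.4**2)


def test_expected_variance_monomorphic_is_zero():
    plan = make_crossing_plan("magic", 4, 300, 6)
    var, _ = expected_qtl_variance(plan, np.array([1, 1, 1, 1]), 0.4)
    assert var == pytest.approx(0.0)


def test_expected_variance_biparental_family():
    plan = make_crossing_plan("diallel", 2, 100, 6)
    var, _ = expected_qtl_variance(plan, np.array([1, 2]), 0.4)
    assert var == pytest.approx(0.4**2)


# ---------------------------------------------------------------------------
# family structure in genotype space
# ---------------------------------------------------------------------------


def test_pca_separates_diallel_families_but_not_magic(study_map):
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    scores = {}
    for design in ("diallel", "magic"):
        rng = np.random.default_rng(99)
        founders = synthetic_founders(study_map, 4, rng)
        plan = default_plan(design)
        mosaics = advance_population(plan, study_map, rng)
        table = realize_genotypes(mosaics, founders, study_map, 0.0)
        pcs = PCA(n_components=2).fit_transform(table.dosages)
        if design == "magic":
            # no real families: score random halves as pseudo-families
            labels = np.arange(len(mosaics)) % 2
        else:
            labels = pd.factorize(table.family_labels)[0]
        scores[design] = silhouette_score(pcs, labels)
    assert scores["diallel"] > 0.3
    assert scores["magic"] < 0.1
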