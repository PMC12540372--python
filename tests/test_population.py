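"""Probabilistic CYP2C9 activity sampling and population comparison."""

import math

import numpy as np
import pytest

from glimtwin import engine, nca, population
from glimtwin.population import (
    ActivityDistribution,
    FrequencyTable,
    bundled_frequency_tables,
    compare_populations,
    population_mean_activity,
    sample_allele_activity,
    sample_genotype,
    sample_individual_activity,
    simulate_population,
)

DIST = ActivityDistribution(sigma=0.35)


def test_lognormal_mean_constraint_exact():
    for allele, a in (("*1", 1.0), ("*2", 0.68), ("*3", 0.23)):
        mu = DIST.mu(allele)
        assert math.exp(mu + DIST.sigma**2 / 2) == pytest.approx(a, abs=1e-12)


def test_unknown_allele_rejected():
    with pytest.raises(ValueError):
        DIST.mu("*5")


def test_allele_draw_mean_and_positivity(rng):
    draws = np.array([sample_allele_activity("*1", DIST, rng)
                      for _ in range(100_000)])
    assert np.all(draws > 0)
    assert draws.mean() == pytest.approx(1.0, abs=0.01)


def test_sigma_zero_degenerates_to_fixed_activity(rng):
    dist0 = ActivityDistribution(sigma=0.0)
    assert sample_allele_activity("*2", dist0, rng) == pytest.approx(0.68)
    assert sample_individual_activity("*1/*1", dist0, rng) == pytest.approx(1.0)


def test_individual_activity_mean_matches_fixed_diplotype(rng):
    draws = np.array([sample_individual_activity("*1/*3", DIST, rng)
                      for _ in range(100_000)])
    assert draws.mean() == pytest.approx(0.615, abs=0.01)


def test_homozygote_variance_halved_by_averaging(rng):
    alleles = np.array([sample_allele_activity("*1", DIST, rng)
                        for _ in range(50_000)])
    indiv = np.array([sample_individual_activity("*1/*1", DIST, rng)
                      for _ in range(50_000)])
    assert indiv.var() == pytest.approx(alleles.var() / 2.0, rel=0.05)


def test_hardy_weinberg_expansion():
    t = FrequencyTable.from_alleles(
        "demo", {"*1": 0.7, "*2": 0.2, "*3": 0.1})
    assert t.genotypes["*1/*2"] == pytest.approx(2 * 0.7 * 0.2)
    assert t.genotypes["*1/*1"] == pytest.approx(0.49)
    assert t.genotypes["*3/*3"] == pytest.approx(0.01)
    assert sum(t.genotypes.values()) == pytest.approx(1.0, abs=1e-12)


def test_invalid_frequency_tables_rejected():
    with pytest.raises(ValueError, match="sum"):
        FrequencyTable("bad", {"*1/*1": 0.5, "*1/*2": 0.4})
    with pytest.raises(ValueError, match="sum"):
        FrequencyTable.from_alleles("bad", {"*1": 0.5, "*2": 0.4})


def test_degenerate_table_always_draws_same_genotype(rng):
    t = FrequencyTable("wt", {"*1/*1": 1.0})
    assert all(sample_genotype(t, rng) == "*1/*1" for _ in range(50))


def test_empirical_genotype_frequencies_converge(rng):
    t = FrequencyTable.from_alleles("demo", {"*1": 0.776, "*2": 0.114,
                                             "*3": 0.110})
    draws = [sample_genotype(t, rng) for _ in range(100_000)]
    for g, f in t.genotypes.items():
        emp = sum(d == g for d in draws) / len(draws)
        assert abs(emp - f) < 0.01


def test_population_mean_activity_wildtype_and_printed_group():
    assert population_mean_activity(FrequencyTable("wt", {"*1/*1": 1.0})) == 1.0
    csa = FrequencyTable.from_alleles(
        "Central/South Asian", {"*1": 0.776, "*2": 0.114, "*3": 0.110})
    assert round(population_mean_activity(csa), 2) == 0.88


def test_mean_activity_linear_in_frequencies():
    a = FrequencyTable("a", {"*1/*1": 1.0})
    b = FrequencyTable("b", {"*3/*3": 1.0})
    mix = FrequencyTable("mix", {"*1/*1": 0.25, "*3/*3": 0.75})
    assert population_mean_activity(mix) == pytest.approx(
        0.25 * population_mean_activity(a) + 0.75 * population_mean_activity(b))


def test_mean_activity_matches_monte_carlo(rng):
    t = FrequencyTable.from_alleles("demo", {"*1": 0.8, "*2": 0.1, "*3": 0.1})
    draws = [sample_individual_activity(sample_genotype(t, rng), DIST, rng)
             for _ in range(100_000)]
    assert np.mean(draws) == pytest.approx(population_mean_activity(t),
                                           abs=0.005)


def test_bundled_tables_valid_and_nine_groups():
    tables = bundled_frequency_tables()
    assert len(tables) == 9
    for t in tables.values():
        assert sum(t.genotypes.values()) == pytest.approx(1.0, abs=1e-9)
    assert round(tables["Central/South Asian"].mean_activity(), 2) == 0.88
    assert round(tables["Oceanian"].mean_activity(), 2) == 0.98


def test_degenerate_population_matches_reference_simulation(ref):
    t = FrequencyTable("wt", {"*1/*1": 1.0})
    res = simulate_population(t, n=1, dose_mg=4.0,
                              dist=ActivityDistribution(sigma=0.0), seed=1)
    sim = engine.single_oral_dose(ref, 4.0, rtol=1e-6, atol=1e-9,
                                  dt_out=0.25)
    pk = nca.pk_from_result(sim, "gli")
    row = res.individuals.iloc[0]
    assert row["f_cyp2c9"] == pytest.approx(1.0)
    assert row["gli_auc"] == pytest.approx(pk.auc_0_inf, rel=1e-9)
    assert res.n_failed == 0


def test_population_deterministic_under_seed():
    t = bundled_frequency_tables()["European"]
    r1 = simulate_population(t, n=25, seed=42)
    r2 = simulate_population(t, n=25, seed=42)
    assert r1.individuals.equals(r2.individuals)


def test_compare_identical_populations():
    t = FrequencyTable("wt", {"*1/*1": 1.0})
    r = simulate_population(t, n=20, seed=3)
    r2 = simulate_population(t, n=20, seed=3)
    r2.name = "wt-copy"
    table = compare_populations([r, r2])
    assert table.loc[0, "ks_statistic"] == 0.0
    assert table.loc[0, "rel_mean_diff_pct"] == 0.0
    assert table.loc[0, "p_holm"] == 1.0


def test_compare_requires_shared_metric():
    t = FrequencyTable("wt", {"*1/*1": 1.0})
    r = simulate_population(t, n=3, seed=0)
    with pytest.raises(ValueError, match="at least 2"):
        compare_populations([r])
    with pytest.raises(ValueError, match="metric"):
        compare_populations([r, r], metric="nonexistent")


def test_holm_adjustment_monotone():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = population._holm(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    # order of evidence preserved
    assert adj[0] <= adj[2] <= adj[1]
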