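"""Tests of the forward Wright-Fisher machinery against population-genetic
closed forms and structural invariants."""

import numpy as np
import pytest

from cavedate import (
    DemographicParams,
    WrightFisherSimulator,
    expected_fixation_time,
)


@pytest.fixture
def sim():
    return WrightFisherSimulator(DemographicParams(), seed=7)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def test_mutation_input_arithmetic():
    p = DemographicParams()
    assert p.mutation_input(10_000) == (400.0, 5e-5)
    assert p.mutation_input(1250) == (50.0, 4e-4)


@pytest.mark.parametrize("kw", [
    dict(n_cf=0),
    dict(g_sf=0),
    dict(mig_frac=1.5),
    dict(u=-0.1),
    dict(checkpoint_years=101),     # not a multiple of both generation times
])
def test_invalid_parameters_rejected(kw):
    with pytest.raises(ValueError):
        DemographicParams(**kw)


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------

def test_absorbing_states_without_mutation(sim):
    freqs = np.array([0.0, 1.0, 0.0, 1.0])
    out = sim.step_generation(freqs, n=100, u=0.0)
    assert np.array_equal(out, freqs)


def test_mutation_input_poisson_mean(sim):
    # appended loci per generation average 2Nu at frequency 1/(2N)
    n, u = 1000, 0.02
    added = []
    for _ in range(300):
        out = sim.step_generation(np.empty(0), n=n, u=u)
        added.append(out.size)
        assert np.all(out == 1.0 / (2 * n))
    mean = np.mean(added)
    se = np.std(added) / np.sqrt(len(added))
    assert abs(mean - 2 * n * u) < 4 * se + 1e-9


def test_heterozygosity_decays_at_one_over_two_n_per_generation(sim):
    """E[2p(1-p)] shrinks by (1 - 1/2N) each generation of pure drift."""
    n, p0, gens, nloci = 25, 0.3, 40, 40_000
    freqs = np.full(nloci, p0)
    for _ in range(gens):
        freqs = sim.step_generation(freqs, n=n, u=0.0)
    het = 2 * freqs * (1 - freqs)
    expected = 2 * p0 * (1 - p0) * (1 - 1 / (2 * n)) ** gens
    se = het.std() / np.sqrt(nloci)
    assert abs(het.mean() - expected) < 4 * se


def test_migration_is_linear_admixture(sim):
    cf = np.array([0.0, 0.2, 1.0])
    sf = np.array([0.5, 0.8, 0.0])
    assert np.array_equal(sim.migrate(cf, sf, 0.0), cf)
    assert np.array_equal(sim.migrate(cf, sf, 1.0), sf)
    np.testing.assert_allclose(
        sim.migrate(np.array([0.0]), np.array([0.5]), 0.01), [0.005]
    )
    with pytest.raises(ValueError):
        sim.migrate(cf, sf, -0.1)


def test_lab_sample_edge_cases():
    p = DemographicParams()
    sim = WrightFisherSimulator(p, seed=3)
    assert np.all(sim.lab_sample(np.zeros(100)) == 0.0)
    assert np.all(sim.lab_sample(np.ones(100)) == 1.0)
    # without lab drift the sample is a plain binomial(2*n_fish, p)/2*n_fish
    sim0 = WrightFisherSimulator(p.with_(lab_gens=0), seed=3)
    lab = sim0.lab_sample(np.full(200_000, 0.3))
    assert abs(lab.mean() - 0.3) < 0.002
    np.testing.assert_allclose(lab.var(), 0.3 * 0.7 / 20, rtol=0.02)


def test_lab_sample_variance_after_drift():
    """Sampling plus t lab generations compounds drift variance to
    p(1-p)(1 - (1 - 1/2N)^(t+1)) when sample size equals lab Ne."""
    p0, reps = 0.4, 200_000
    prm = DemographicParams()
    sim = WrightFisherSimulator(prm, seed=9)
    lab = sim.lab_sample(np.full(reps, p0))
    expected = p0 * (1 - p0) * (1 - (1 - 1 / 20) ** (prm.lab_gens + 1))
    np.testing.assert_allclose(lab.var(), expected, rtol=0.02)


# ---------------------------------------------------------------------------
# classification of simulated loci
# ---------------------------------------------------------------------------

def test_classify_simulated_patterns(sim):
    lab_sf = np.array([0.0, 1.0, 0.0, 1.0, 0.5, 0.5, 0.5, 0.0, 1.0, 0.05])
    lab_cf = np.array([1.0, 0.0, 0.5, 0.5, 0.0, 1.0, 0.5, 0.0, 1.0, 0.5])
    classes, stats = sim.classify_simulated(lab_sf, lab_cf)
    #            1  2  3  4  5  6  7  excl excl  3 (singleton counts as fixed)
    assert list(classes) == [1, 2, 3, 4, 5, 6, 7, 0, 0, 3]
    assert stats.total == 8
    with pytest.raises(ValueError):
        sim.classify_simulated(lab_sf, lab_cf[:-1])


def test_all_loci_fixed_opposite_gives_pure_class_1(sim):
    classes, stats = sim.classify_simulated(np.zeros(50), np.ones(50))
    assert stats.class_freqs[0] == 1.0


def test_divergent_class_never_occurs_in_simulation(sim):
    # structural: one mutant allele per locus admits classes 1-7 only
    rng = np.random.default_rng(0)
    lab_sf = rng.integers(0, 21, 5000) / 20
    lab_cf = rng.integers(0, 21, 5000) / 20
    classes, stats = sim.classify_simulated(lab_sf, lab_cf)
    assert classes.max() <= 7
    assert len(stats.class_counts) == 7


def test_classify_simulated_agrees_with_site_level_classifier(sim):
    """Dual route: the vectorized lab classifier must match per-site
    classification with explicit allele-frequency mappings."""
    from cavedate import classify_site

    rng = np.random.default_rng(5)
    lab_sf = rng.integers(0, 21, 400) / 20
    lab_cf = rng.integers(0, 21, 400) / 20
    classes, _ = sim.classify_simulated(lab_sf, lab_cf)
    for f_sf, f_cf, got in zip(lab_sf, lab_cf, classes):
        want = classify_site({"A": 1 - f_sf, "G": f_sf},
                             {"A": 1 - f_cf, "G": f_cf},
                             ancestral="A", maf_min=0.05)
        assert got == want


def test_expected_lab_counts_match_monte_carlo_sampling(sim):
    """Dual route: the exact expectation of the lab observation layer must
    agree with the average of many sampled lab classifications."""
    rng = np.random.default_rng(17)
    n = 1500
    fsf, fcf = rng.random(n), rng.random(n)
    exp = sim.expected_lab_class_counts(fsf, fcf)
    acc = np.zeros(7)
    reps = 250
    for _ in range(reps):
        cl = sim.classify_simulated(sim.lab_sample(fsf),
                                    sim.lab_sample(fcf))[0]
        acc += np.bincount(cl, minlength=8)[1:8]
    mc = acc / reps
    assert np.all(np.abs(exp - mc) / np.maximum(mc, 10) < 0.05)


def test_lab_state_operator_is_stochastic_and_symmetric(sim):
    op = sim._lab_state_operator()
    np.testing.assert_allclose(op.sum(axis=1), 1.0, atol=1e-12)
    # allele-label symmetry: reversing the sample count swaps anc and der
    np.testing.assert_allclose(op, op[::-1, [2, 1, 0]], atol=1e-12)


def test_expected_counts_obey_population_exchange(sim):
    rng = np.random.default_rng(23)
    fsf, fcf = rng.random(300), rng.random(300)
    fwd = sim.expected_lab_class_counts(fsf, fcf)
    rev = sim.expected_lab_class_counts(fcf, fsf)
    # classes permute as (1 2)(3 5)(4 6), class 7 fixed
    np.testing.assert_allclose(rev, fwd[[1, 0, 4, 5, 2, 3, 6]], rtol=1e-10)


# ---------------------------------------------------------------------------
# burn-in
# ---------------------------------------------------------------------------

def test_burn_in_without_mutation_is_empty():
    p = DemographicParams(n_anc=100, u=0.0, burn_in_gens=50)
    sim = WrightFisherSimulator(p, seed=1)
    assert sim.burn_in().size == 0


def test_burn_in_segregating_sites_match_infinite_sites_expectation():
    """At equilibrium the segregating-locus count fluctuates around
    4*N*u*sum_{i<2N} 1/i (infinite-sites neutral expectation)."""
    n, u = 400, 0.02
    p = DemographicParams(n_anc=n, u=u)
    sim = WrightFisherSimulator(p, seed=42)
    freqs = sim.burn_in(record_history=True)
    assert sim.burn_in_stationary_
    expected = 4 * n * u * np.sum(1.0 / np.arange(1, 2 * n))
    observed = sim.burn_in_history_[-p.n_anc:].mean()   # time-average tail
    assert abs(observed - expected) / expected < 0.10
    assert np.all((freqs > 0) & (freqs < 1))


# ---------------------------------------------------------------------------
# fixation formula
# ---------------------------------------------------------------------------

def test_expected_fixation_time_limits():
    # nearly fixed alleles fix almost immediately
    assert expected_fixation_time(1 - 1e-9, 1000) < 1e-2
    # a new mutation needs about 4N generations
    n = 50_000
    t = expected_fixation_time(1.0 / (2 * n), n)
    assert abs(t - 4 * n) / (4 * n) < 1e-4
    for bad in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            expected_fixation_time(bad, 100)


# ---------------------------------------------------------------------------
# run_split structure
# ---------------------------------------------------------------------------

def test_checkpoint_years_and_horizon(small_params):
    sim = WrightFisherSimulator(small_params, seed=2)
    traj = sim.run_split()
    years = traj.table["year"].to_numpy()
    k = np.arange(len(years))
    assert np.array_equal(years, k * small_params.checkpoint_years)
    assert years[-1] == small_params.max_years
    with pytest.raises(ValueError):
        WrightFisherSimulator(small_params.with_(max_years=50), seed=2).run_split()


def test_run_split_is_reproducible_given_seed(small_params):
    p = small_params.with_(max_years=1000)
    t1 = WrightFisherSimulator(p, seed=123).run_split()
    t2 = WrightFisherSimulator(p, seed=123).run_split()
    assert t1.table.equals(t2.table)


def test_symmetric_populations_give_exchangeable_class_frequencies():
    """With equal sizes, equal generation times and no migration the
    expected class-frequency vector is invariant under the population
    exchange permutation (1<->2, 3<->5, 4<->6)."""
    p = DemographicParams(n_anc=600, n_sf=600, n_cf=600, g_sf=2, g_cf=2,
                          mig_prob_per_year=0.0, max_years=2000,
                          checkpoint_years=100)
    sim = WrightFisherSimulator(p, seed=31)
    tb = sim.run_split().table
    # aggregate over checkpoints to beat sampling noise
    w = tb["n_classified"].to_numpy()[:, None]
    f = (tb[[f"freq_{k}" for k in range(1, 8)]].to_numpy() * w).sum(0) / w.sum()
    for a, b in ((1, 2), (3, 5), (4, 6)):
        denom = f[a - 1] + f[b - 1]
        assert abs(f[a - 1] - f[b - 1]) / denom < 0.25
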