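"""Neutral sampling formula, MLE, urn simulation, Preston binning and GOF."""

import math

import numpy as np
import pytest

from amfassembly import (
    SAD,
    etienne_logprob,
    ewens_logprob,
    fit_neutral,
    neutral_gof,
    preston_bin,
    simulate_neutral_sad,
)
from amfassembly.neutral_model import _CachedSAD, log_kda
from conftest import partitions


# ---------------------------------------------------------------------------
# Ewens formula (strong-immigration oracle)
# ---------------------------------------------------------------------------

def test_ewens_single_individual():
    assert ewens_logprob(SAD(np.array([1])), theta=3.7) == pytest.approx(0.0)


def test_ewens_two_singletons_closed_form():
    # P(two species among two individuals) = theta / (theta + 1)
    for theta in (0.5, 1.0, 4.0):
        expect = math.log(theta / (theta + 1))
        assert ewens_logprob(SAD(np.array([1, 1])), theta) == pytest.approx(expect)


@pytest.mark.parametrize("theta", [0.5, 1.0, 5.0])
def test_ewens_normalizes_over_partitions(theta):
    total = sum(
        math.exp(ewens_logprob(SAD(np.array(p)), theta)) for p in partitions(4)
    )
    assert total == pytest.approx(1.0, abs=1e-12)


def test_ewens_rejects_bad_theta():
    with pytest.raises(ValueError):
        ewens_logprob(SAD(np.array([2, 1])), 0.0)


# ---------------------------------------------------------------------------
# Etienne formula
# ---------------------------------------------------------------------------

def test_etienne_closed_form_j2():
    # urn enumeration: P(monodominant pair) = 1/(I+1) + I/(I+1) * 1/(theta+1)
    assert etienne_logprob(SAD(np.array([2])), 1.0, 1.0) == pytest.approx(math.log(0.75))
    assert etienne_logprob(SAD(np.array([1, 1])), 1.0, 1.0) == pytest.approx(math.log(0.25))


@pytest.mark.parametrize("theta,I", [(0.5, 1.0), (1.0, 1.0), (5.0, 10.0)])
@pytest.mark.parametrize("J", [2, 3, 4, 5])
def test_etienne_normalizes_over_partitions(theta, I, J):
    """exp(logL) sums to one over every abundance configuration of J."""
    total = sum(
        math.exp(etienne_logprob(SAD(np.array(p)), theta, I)) for p in partitions(J)
    )
    assert total == pytest.approx(1.0, abs=1e-10)


def test_etienne_reduces_to_ewens_at_large_I():
    sad = SAD(np.array([3, 1]))
    for theta in (0.7, 2.0):
        assert etienne_logprob(sad, theta, 1e6) == pytest.approx(
            ewens_logprob(sad, theta), abs=1e-3
        )


def test_kda_nonnegative_and_boundary():
    """K(D, A) >= 0; the A = S boundary term is prod 1/(n_i - 1)! * (0)!*s(n,1)...

    At A = S every species has a_i = 1, so K(D, S) = prod s(n_i, 1) * 0! /
    (n_i - 1)! = prod (n_i - 1)!/(n_i - 1)! = 1.
    """
    sad = SAD(np.array([5, 3, 2, 1]))
    logk = log_kda(sad)
    assert np.all(np.isfinite(logk))  # positivity: finite logs
    assert logk[0] == pytest.approx(0.0, abs=1e-12)  # K(D, S) = 1
    assert logk.size == sad.J - sad.S + 1


def test_etienne_rejects_bad_parameters():
    with pytest.raises(ValueError):
        etienne_logprob(SAD(np.array([2, 1])), -1.0, 1.0)
    with pytest.raises(ValueError):
        etienne_logprob(SAD(np.array([2, 1])), 1.0, 0.0)


# ---------------------------------------------------------------------------
# Maximum likelihood fit
# ---------------------------------------------------------------------------

def test_fit_neutral_beats_nearby_parameters(rng):
    sad = simulate_neutral_sad(8.0, 6.0, 300, rng)
    fit = fit_neutral(sad)
    cached = _CachedSAD(sad)
    assert fit.converged
    assert fit.logL == pytest.approx(cached.logprob(fit.theta, fit.I))
    for f in (0.7, 1.4):
        assert fit.logL >= cached.logprob(fit.theta * f, fit.I) - 1e-9
        assert fit.logL >= cached.logprob(fit.theta, fit.I * f) - 1e-9
    assert 0 < fit.m < 1


def test_fit_neutral_requires_two_species():
    with pytest.raises(ValueError):
        fit_neutral(SAD(np.array([10])))


def test_fit_table1_focal_matches_exact_mle(pooled_sads):
    """The focal-root pooled SAD has a single, grid-confirmed optimum."""
    sad = SAD.from_counts(pooled_sads["focal"])
    assert (sad.J, sad.S) == (503, 26)
    fit = fit_neutral(sad)
    cached = _CachedSAD(sad)
    # dense log-grid around the fit never beats it
    for lt in np.linspace(math.log(fit.theta) - 1, math.log(fit.theta) + 1, 9):
        for li in np.linspace(math.log(fit.I) - 1, math.log(fit.I) + 1, 9):
            assert cached.logprob(math.exp(lt), math.exp(li)) <= fit.logL + 1e-9


# ---------------------------------------------------------------------------
# Urn simulator
# ---------------------------------------------------------------------------

def test_simulator_trivial_cases(rng):
    assert simulate_neutral_sad(1.0, 1.0, 1, rng).abundances.tolist() == [1]
    # monodominance limit: essentially zero chance of a second species
    sad = simulate_neutral_sad(1e-6, 1.0, 100, rng)
    assert sad.S == 1 and sad.J == 100


def test_simulator_matches_exact_probabilities_j3(rng):
    """Frequencies over 20k draws agree with the sampling formula (3 sigma)."""
    n = 20000
    theta, I = 2.0, 3.0
    counts = {}
    for _ in range(n):
        key = tuple(simulate_neutral_sad(theta, I, 3, rng).abundances.tolist())
        counts[key] = counts.get(key, 0) + 1
    for p in partitions(3):
        exact = math.exp(etienne_logprob(SAD(np.array(p)), theta, I))
        emp = counts.get(p, 0) / n
        sigma = math.sqrt(exact * (1 - exact) / n)
        assert abs(emp - exact) < 3 * sigma + 1e-9


def test_simulator_reproducible_and_conserves_J():
    a = simulate_neutral_sad(4.0, 3.0, 250, np.random.default_rng(11))
    b = simulate_neutral_sad(4.0, 3.0, 250, np.random.default_rng(11))
    assert a.abundances.tolist() == b.abundances.tolist()
    assert a.J == 250


# ---------------------------------------------------------------------------
# Preston octaves
# ---------------------------------------------------------------------------

def test_preston_basic_binning():
    b = preston_bin(SAD(np.array([1, 1, 2, 4, 8])))
    assert b.species_count.tolist() == [2.0, 1.0, 1.0, 1.0]


def test_preston_split_boundary():
    b = preston_bin(SAD(np.array([2])), split=True)
    assert b.species_count[1] == pytest.approx(0.5)
    assert b.species_count[2] == pytest.approx(0.5)


def test_preston_conserves_species_count(rng):
    for _ in range(5):
        sad = simulate_neutral_sad(5.0, 5.0, 200, rng)
        for split in (False, True):
            b = preston_bin(sad, split=split)
            assert b.species_count.sum() == pytest.approx(sad.S)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def test_gof_zero_chi2_when_observation_matches_expectation(monkeypatch, rng):
    """If simulated octaves exactly reproduce the observed ones, chi2 = 0."""
    import amfassembly.neutral_model as nm

    sad = SAD(np.array([8, 4, 2, 1, 1]))
    fit = fit_neutral(sad)
    monkeypatch.setattr(
        nm, "simulate_neutral_sad", lambda *a, **k: SAD(sad.abundances.copy())
    )
    gof = nm.neutral_gof(sad, fit, n_sims=5, seed=0, split=False)
    assert gof.chi2 == pytest.approx(0.0)
    assert gof.df == 4 - 1  # octaves 0..3 occupied
    assert gof.chi2_P == pytest.approx(1.0)


def test_gof_reports_reasonable_fields(pooled_sads):
    sad = SAD.from_counts(pooled_sads["neighborhood"])
    fit = fit_neutral(sad)
    gof = neutral_gof(sad, fit, n_sims=50, seed=1)
    assert gof.chi2 >= 0 and gof.df >= 1
    assert 0 <= gof.ks_D <= 1
    assert 0 < gof.chi2_P <= 1 and 0 < gof.ks_P <= 1
    assert gof.expected_octaves.shape == gof.observed_octaves.shape
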