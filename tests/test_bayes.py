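"""Partition enumeration and the trans-ethnic Bayes factor."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import comb

from transmeta.bayes import (
    cluster_log_marginal,
    enumerate_partitions,
    partition_prior_from_distance,
    transethnic_bf,
    wakefield_log10_abf,
)
from transmeta.exceptions import PartitionExplosionError
from transmeta.meta import StudyEstimate


def bell_numbers(kmax):
    """Bell-number recurrence: B(n+1) = sum_k C(n,k) B(k)."""
    bell = [1]
    for n in range(kmax):
        bell.append(int(sum(comb(n, k, exact=True) * bell[k] for k in range(n + 1))))
    return bell[1:]


class TestEnumeration:
    def test_counts_match_bell_numbers(self):
        bells = bell_numbers(6)
        for k in range(1, 7):
            labels = [f"p{i}" for i in range(k)]
            assert len(enumerate_partitions(labels)) == bells[k - 1]

    def test_partitions_are_disjoint_covers(self):
        labels = ["A", "B", "C"]
        parts = enumerate_partitions(labels)
        assert len(parts) == 5
        seen = set()
        for part in parts:
            flat = [l for cl in part for l in cl]
            assert sorted(flat) == sorted(labels)  # disjoint cover
            seen.add(frozenset(frozenset(cl) for cl in part))
        assert len(seen) == 5  # all distinct

    def test_guard_against_combinatorial_explosion(self):
        with pytest.raises(PartitionExplosionError):
            enumerate_partitions([f"p{i}" for i in range(11)])


def quad_cluster_marginal(betas, ses, sigma):
    def integrand(mu):
        return math.exp(
            sum(stats.norm.logpdf(b, mu, s) for b, s in zip(betas, ses))
            + stats.norm.logpdf(mu, 0, sigma)
        )

    # hint the integrator at the posterior mode (the integrand can be a
    # very narrow spike relative to the integration range)
    w = np.asarray([1 / s**2 for s in ses])
    mode = float(np.sum(w * np.asarray(betas)) / (np.sum(w) + 1 / sigma**2))
    val, _ = integrate.quad(integrand, -30, 30, limit=400, points=[mode])
    return math.log(val)


class TestClusterMarginal:
    def test_sigma_zero_is_the_null_likelihood(self):
        betas, ses = [0.5, -0.2], [0.3, 0.4]
        expect = sum(stats.norm.logpdf(b, 0, s) for b, s in zip(betas, ses))
        assert cluster_log_marginal(betas, ses, 0.0) == pytest.approx(expect, abs=1e-12)

    def test_matches_adaptive_quadrature(self, rng):
        for _ in range(8):
            k = int(rng.integers(1, 5))
            betas = rng.normal(0, 1.5, k)
            ses = rng.uniform(0.2, 2.0, k)
            sigma = float(rng.uniform(0.1, 2.0))
            assert cluster_log_marginal(betas, ses, sigma) == pytest.approx(
                quad_cluster_marginal(betas, ses, sigma), abs=1e-8
            )

    def test_single_study_reduces_to_wakefield_abf(self, rng):
        for _ in range(10):
            beta = float(rng.normal(0, 2))
            se = float(rng.uniform(0.1, 1.5))
            sigma = float(rng.uniform(0.1, 2.0))
            log_bf = cluster_log_marginal([beta], [se], sigma) - cluster_log_marginal(
                [beta], [se], 0.0
            )
            assert log_bf / math.log(10) == pytest.approx(
                wakefield_log10_abf(beta, se, sigma), abs=1e-8
            )

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            cluster_log_marginal([1.0], [0.0], 0.5)
        with pytest.raises(ValueError):
            cluster_log_marginal([1.0], [1.0], -0.1)


def ests(betas, ses):
    return [StudyEstimate(f"p{i}", b, s) for i, (b, s) in enumerate(zip(betas, ses))]


class TestTransethnicBF:
    def test_null_inputs_do_not_favour_association(self):
        r = transethnic_bf(ests([0.0] * 4, [1.0] * 4), sigma=1.0)
        assert r.log10_bf <= 0.0

    def test_homogeneous_strong_signal(self):
        # z ~ 5 in every population
        r = transethnic_bf(ests([5.0] * 4, [1.0] * 4), sigma=2.0)
        assert r.log10_bf > 1.5
        top_part, _ = r.top_partitions(1)[0]
        assert len(top_part) == 1  # one shared-effect cluster dominates

    def test_monotone_in_signal_scale(self):
        base = np.array([0.5, 0.8, 0.3, 0.6])
        ses = [0.5] * 4
        bfs = [
            transethnic_bf(ests(scale * base, ses), sigma=1.0).log10_bf
            for scale in np.linspace(0.0, 4.0, 9)
        ]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(bfs, bfs[1:]))

    def test_allele_flip_invariance(self):
        betas, ses = [0.4, -0.2, 0.7], [0.3, 0.5, 0.4]
        a = transethnic_bf(ests(betas, ses), sigma=0.8)
        b = transethnic_bf(ests([-x for x in betas], ses), sigma=0.8)
        assert a.log10_bf == pytest.approx(b.log10_bf, abs=1e-12)

    def test_posterior_weights_normalised(self, rng):
        r = transethnic_bf(ests(rng.normal(0, 1, 5), rng.uniform(0.2, 1, 5)), sigma=0.7)
        assert abs(r.posterior_weights.sum() - 1.0) < 1e-12
        assert len(r.partitions) == 52  # Bell(5)

    def test_matches_full_quadrature_oracle(self, rng):
        # independent route: per-cluster quadrature + explicit partition sum
        betas = rng.normal(0, 1, 4)
        ses = rng.uniform(0.3, 1.2, 4)
        sigma = 0.9
        labels = [f"p{i}" for i in range(4)]
        lookup = dict(zip(labels, zip(betas, ses)))
        parts = enumerate_partitions(labels)
        logms = []
        for part in parts:
            lm = 0.0
            for cl in part:
                bs = [lookup[l][0] for l in cl]
                ss = [lookup[l][1] for l in cl]
                lm += quad_cluster_marginal(bs, ss, sigma)
            logms.append(lm + math.log(1.0 / len(parts)))
        log_model = np.logaddexp.reduce(logms)
        log_null = sum(stats.norm.logpdf(b, 0, s) for b, s in zip(betas, ses))
        expected = (log_model - log_null) / math.log(10)
        r = transethnic_bf(ests(betas, ses), sigma=sigma)
        assert r.log10_bf == pytest.approx(expected, abs=1e-6)

    def test_distance_prior_hook(self):
        labels = ["a", "b", "c"]
        parts = enumerate_partitions(labels)
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        w0 = partition_prior_from_distance(parts, labels, d, concentration=0.0)
        assert np.allclose(w0, 1.0 / len(parts))
        w = partition_prior_from_distance(parts, labels, d, concentration=1.0)
        assert abs(w.sum() - 1.0) < 1e-12
        # the all-singletons partition (no within-cluster distance) gains weight
        singleton = parts.index((("a",), ("b",), ("c",)))
        assert w[singleton] > w0[singleton]
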