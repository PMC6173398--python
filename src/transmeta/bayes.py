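"""Trans-ethnic Bayesian meta-analysis (MANTRA-style, exact enumeration).

The model: per-population effect estimates ``beta_i`` with standard
errors ``se_i`` are combined under a mixture over *set partitions* of
the populations into effect-sharing clusters.  Within a cluster the
populations share one latent effect ``mu ~ N(0, sigma^2)``; across
clusters effects are independent.  The null fixes every effect at 0.
The association evidence is the log10 Bayes factor

    log10 BF = log10( sum_partitions prior(P) * prod_clusters m_c / m_0 )

where ``m_c`` is the closed-form Gaussian marginal likelihood of a
cluster and ``m_0`` the null likelihood.  With K <= 10 populations the
partition sum is exhaustive (Bell(K) terms), so results carry no Monte
Carlo error — this replaces the MCMC the original MANTRA software uses,
which is only needed at genome scale.

The partition prior defaults to uniform.  A hook accepts a pairwise
population-distance matrix and a concentration parameter, down-weighting
partitions that cluster distant populations together; the original
method derives such distances from genome-wide allele frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import PartitionExplosionError
from .meta import StudyEstimate

_LN10 = math.log(10.0)

#: Guard for exhaustive enumeration: Bell(10) = 115975 partitions.
MAX_POPULATIONS = 10


@dataclass(frozen=True)
class BayesFactorResult:
    """log10 Bayes factor with its per-partition decomposition."""

    log10_bf: float
    partitions: tuple  # tuple of partitions; each a tuple of label-tuples
    log_marginals: np.ndarray  # log marginal likelihood per partition
    prior_weights: np.ndarray
    posterior_weights: np.ndarray

    def top_partitions(self, m: int = 3):
        """The ``m`` partitions with the largest posterior weight."""
        order = np.argsort(self.posterior_weights)[::-1][:m]
        return [(self.partitions[i], float(self.posterior_weights[i])) for i in order]


def enumerate_partitions(labels: Sequence[str]):
    """All set partitions of ``labels`` (count = Bell(K)); K <= 10.

    Each partition is a tuple of clusters; each cluster a tuple of
    labels in input order.  Enumeration order is deterministic.
    """
    labels = list(labels)
    k = len(labels)
    if k < 1:
        raise ValueError("need at least one population label")
    if k > MAX_POPULATIONS:
        raise PartitionExplosionError(
            f"{k} populations would require Bell({k}) partitions; exhaustive "
            f"enumeration is capped at K={MAX_POPULATIONS}. Reduce the number "
            "of populations (a partition-sampling mode is not implemented)."
        )
    partitions = [[[labels[0]]]]
    for lab in labels[1:]:
        nxt = []
        for part in partitions:
            for i in range(len(part)):
                nxt.append([c[:] for c in part[:i]] + [part[i] + [lab]] + [c[:] for c in part[i + 1:]])
            nxt.append([c[:] for c in part] + [[lab]])
        partitions = nxt
    return [tuple(tuple(c) for c in part) for part in partitions]


def cluster_log_marginal(betas, ses, sigma: float) -> float:
    """Log marginal likelihood of one effect-sharing cluster.

    Closed form of ``log ∫ prod_i N(beta_i; mu, se_i^2) N(mu; 0, sigma^2) dmu``.
    ``sigma = 0`` collapses the prior to a point mass at 0 and returns the
    null log-likelihood ``sum_i log N(beta_i; 0, se_i^2)``.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    if sigma < 0:
        raise ValueError("effect-prior SD must be non-negative")
    w = 1.0 / ses**2
    base = float(-0.5 * np.sum(np.log(2.0 * math.pi * ses**2)))
    c0 = float(np.sum(w * betas**2))
    if sigma == 0.0:
        return base - 0.5 * c0
    a = float(np.sum(w)) + 1.0 / sigma**2
    b = float(np.sum(w * betas))
    # complete the square in mu; the 2*pi factors from prior and integral
    # combine to -0.5*log(sigma^2 * a)
    return base - 0.5 * math.log(sigma**2 * a) - 0.5 * (c0 - b**2 / a)


def partition_prior_from_distance(
    partitions, labels: Sequence[str], distance: np.ndarray, concentration: float
) -> np.ndarray:
    """Prior weights favouring partitions that cluster nearby populations.

    weight(P) ∝ exp(-concentration * sum of within-cluster pairwise
    distances).  ``concentration = 0`` recovers the uniform prior.
    """
    distance = np.asarray(distance, dtype=float)
    idx = {lab: i for i, lab in enumerate(labels)}
    scores = np.empty(len(partitions))
    for p, part in enumerate(partitions):
        s = 0.0
        for cluster in part:
            ii = [idx[lab] for lab in cluster]
            for a in range(len(ii)):
                for b in range(a + 1, len(ii)):
                    s += distance[ii[a], ii[b]]
        scores[p] = s
    logw = -concentration * scores
    return np.exp(logw - logsumexp(logw))


def transethnic_bf(
    estimates: Sequence[StudyEstimate],
    sigma: float,
    prior_weights: Optional[np.ndarray] = None,
    distance: Optional[np.ndarray] = None,
    concentration: float = 1.0,
) -> BayesFactorResult:
    """log10 Bayes factor for association across populations.

    Parameters
    ----------
    estimates : per-population (beta, se) rows (k >= 2).
    sigma : SD of the zero-mean Gaussian prior on each cluster's shared
        effect, on the trait-per-allele scale.
    prior_weights : explicit partition prior (must sum to 1); default
        uniform over the Bell(k) partitions.
    distance, concentration : optional pairwise-distance prior hook
        (ignored when ``prior_weights`` is given).
    """
    if len(estimates) < 2:
        raise ValueError("trans-ethnic BF needs at least two populations")
    if sigma <= 0:
        raise ValueError("effect-prior SD must be positive")
    labels = [e.label for e in estimates]
    if len(set(labels)) != len(labels):
        raise ValueError("population labels must be unique")
    betas = {e.label: e.beta for e in estimates}
    ses = {e.label: e.se for e in estimates}

    partitions = tuple(enumerate_partitions(labels))
    if prior_weights is None:
        if distance is not None:
            prior = partition_prior_from_distance(partitions, labels, distance, concentration)
        else:
            prior = np.full(len(partitions), 1.0 / len(partitions))
    else:
        prior = np.asarray(prior_weights, dtype=float)
        if prior.shape != (len(partitions),) or abs(prior.sum() - 1.0) > 1e-9:
            raise ValueError("prior weights must be a distribution over all partitions")

    log_marg = np.array([
        sum(
            cluster_log_marginal([betas[l] for l in cl], [ses[l] for l in cl], sigma)
            for cl in part
        )
        for part in partitions
    ])
    log_model = float(logsumexp(log_marg + np.log(prior)))
    log_null = cluster_log_marginal(
        [betas[l] for l in labels], [ses[l] for l in labels], 0.0
    )
    post = np.exp(log_marg + np.log(prior) - log_model)
    return BayesFactorResult(
        log10_bf=(log_model - log_null) / _LN10,
        partitions=partitions,
        log_marginals=log_marg,
        prior_weights=prior,
        posterior_weights=post,
    )


def wakefield_log10_abf(beta: float, se: float, sigma: float) -> float:
    """Single-study approximate Bayes factor (association vs null), log10.

    ln ABF = 0.5*ln(se^2/(se^2+sigma^2)) + 0.5 * z^2 * sigma^2/(se^2+sigma^2)
    with z = beta/se.  The K=1 trans-ethnic BF reduces to this exactly.
    """
    if se <= 0 or sigma <= 0:
        raise ValueError("se and sigma must be positive")
    z = beta / se
    v, t = se**2, sigma**2
    return (0.5 * math.log(v / (v + t)) + 0.5 * z * z * t / (v + t)) / _LN10
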