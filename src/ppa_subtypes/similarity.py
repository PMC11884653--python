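"""Positional variance, Hellinger distance and randomized reference values.

The positional variance matrix (the data behind a positional variance
diagram) gives, for every event, the posterior probability of each stage
position, estimated as its frequency across MCMC sequence samples.  Two
subtype progression patterns are compared by the mean Hellinger distance
between corresponding event-position distributions,

    H(P, Q) = sqrt(1 - sum_i sqrt(p_i * q_i)),

which is 0 for identical distributions and 1 when the supports are disjoint.
A randomized-model reference value calibrates what "unrelated" looks like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import ConfigurationError, EventSet

__all__ = ["positional_variance", "hellinger", "model_distance",
           "randomized_reference", "RandomizedReference"]


def positional_variance(samples: np.ndarray) -> np.ndarray:
    """Event-by-position posterior frequencies from MCMC sequence samples.

    ``samples`` is (n_samples, n_events), each row a permutation of event
    ids.  Returns a doubly-stochastic (n_events, n_events) matrix whose
    entry (e, s) is the fraction of samples placing event e at position s.
    """
    samples = np.asarray(samples)
    if samples.ndim == 1:
        samples = samples[None, :]
    if samples.ndim != 2 or samples.shape[0] < 1:
        raise ConfigurationError("need at least one sequence sample")
    n_samples, N = samples.shape
    P = np.zeros((N, N))
    pos = np.broadcast_to(np.arange(N), samples.shape)
    np.add.at(P, (samples.ravel(), pos.ravel()), 1.0)
    return P / n_samples


def hellinger(P, Q) -> float:
    """Hellinger distance between two discrete probability distributions."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ConfigurationError("distributions must have the same length")
    if np.any(P < 0) or np.any(Q < 0):
        raise ConfigurationError("distributions must be non-negative")
    for name, x in (("P", P), ("Q", Q)):
        if abs(x.sum() - 1.0) > 1e-8:
            raise ConfigurationError(f"{name} sums to {x.sum():.6g}, not 1")
    bc = float(np.sqrt(P * Q).sum())
    return float(np.sqrt(max(0.0, 1.0 - bc)))


def model_distance(A: np.ndarray, B: np.ndarray, aggregate: str = "mean") -> float:
    """Distance between two positional-variance matrices over a shared event set.

    Per-event Hellinger distances between corresponding rows, aggregated by
    unweighted mean (default) or max.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ConfigurationError("positional-variance matrices must share one event set")
    d = np.array([hellinger(A[e], B[e]) for e in range(A.shape[0])])
    if aggregate == "mean":
        return float(d.mean())
    if aggregate == "max":
        return float(d.max())
    raise ConfigurationError(f"unknown aggregation {aggregate!r}")


@dataclass
class RandomizedReference:
    """Null similarity of randomized models (H0), with Monte-Carlo error."""

    h0_mean: float
    h0_sd: float
    ci_low: float
    ci_high: float
    n_pairs: int
    scheme: str
    seed: int

    def as_dict(self) -> dict:
        return {"h0_mean": self.h0_mean, "h0_sd": self.h0_sd,
                "ci_95": [self.ci_low, self.ci_high], "n_pairs": self.n_pairs,
                "scheme": self.scheme, "seed": self.seed}


def randomized_reference(event_set: EventSet, scheme: str = "delta-permutation",
                         n_pairs: int = 2000, seed: int = 0, W=None,
                         mcmc_iters: int = 500) -> RandomizedReference:
    """Reference distance H0 between pairs of randomized models.

    ``delta-permutation`` pairs independent uniform random orderings of the
    event set (as delta positional-variance matrices); by symmetry each event
    lands on the same position with probability 1/N, so the mean distance
    approaches 1 - 1/N.  The within-biomarker threshold-order constraint is
    deliberately ignored here: the null represents arbitrary orderings, and
    the constraint would bias event-position marginals away from uniform.

    ``permuted-data`` fits single-sequence models to per-biomarker
    row-permuted copies of a supplied w-score matrix (destroying the
    between-region correlation structure) and compares the positional
    variance of seeded refits; slower, but data-driven.
    """
    if n_pairs < 2:
        raise ConfigurationError("n_pairs must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x4E11]))
    N = event_set.n_events

    dists = np.empty(n_pairs)
    if scheme == "delta-permutation":
        for i in range(n_pairs):
            a = rng.permutation(N)
            b = rng.permutation(N)
            # delta PVDs: per-event Hellinger is 0 iff positions agree, else 1
            dists[i] = float(np.mean(a != b))
    elif scheme == "permuted-data":
        if W is None:
            raise ConfigurationError("scheme 'permuted-data' requires a w-score matrix")
        from .model import FitConfig, fit, mcmc

        W = np.asarray(getattr(W, "values", W), dtype=float)
        for i in range(n_pairs):
            pvds = []
            for rep in range(2):
                Wp = np.column_stack([rng.permutation(W[:, j]) for j in range(W.shape[1])])
                m = fit(Wp, event_set, 1, config=FitConfig(n_restarts=2, seed=int(rng.integers(2**31))))
                m = mcmc(Wp, m, n_iter=mcmc_iters, seed=int(rng.integers(2**31)))
                pvds.append(positional_variance(m.mcmc_samples[0]))
            dists[i] = model_distance(pvds[0], pvds[1])
    else:
        raise ConfigurationError(f"unknown randomization scheme {scheme!r}")

    mean = float(dists.mean())
    sd = float(dists.std(ddof=1))
    half = float(1.96 * sd / np.sqrt(n_pairs))
    return RandomizedReference(mean, sd, max(0.0, mean - half), min(1.0, mean + half),
                               n_pairs, scheme, seed)
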