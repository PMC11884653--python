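"""Subtype-and-stage inference over threshold events.

Mixture model: subject ``x`` (a row of w-scores) belongs to subtype ``c`` with
fraction ``f_c`` and sits at an unknown stage ``k`` with a uniform prior over
``0..N_events``.  Given the subtype's event sequence ``S_c``, the likelihood of
``x`` at stage ``k`` is a product of Gaussians centred on the piecewise-linear
trajectory values with per-biomarker noise ``sigma_b`` (1 by default; the
w-scores are already unit-scaled against controls).

Fitting follows the usual schedule for this model family: greedy
event-relocation ascent for a single sequence, hierarchical initialization of
C subtypes by splitting one subtype of the fitted (C-1)-subtype model, EM over
responsibilities / fractions / sequences, then a Metropolis sampler over
sequence space for uncertainty (no burn-in is discarded: the chain starts at
the EM solution).  The number of subtypes is chosen by the cross-validation
information criterion, CVIC(C) = sum over folds of -2 x held-out
log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import build_trajectory, reloc_objectives
from .events import ConfigurationError, EventSet, canonicalize_sequence, trajectory_matrix

__all__ = [
    "SubtypeModel",
    "FitConfig",
    "CVICResult",
    "stage_likelihood",
    "stage_loglik_matrix",
    "data_log_likelihood",
    "fit",
    "fit_hierarchy",
    "mcmc",
    "cross_validate",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# model container


@dataclass
class SubtypeModel:
    """A fitted subtype-and-stage model.

    ``sequences[c]`` is the point-estimate event ordering of subtype ``c``
    (event ids, see :class:`~ppa_subtypes.events.EventSet`), ``fractions[c]``
    its mixture weight.  ``mcmc_samples[c]``, if present, is an
    ``(n_iter, n_events)`` integer array of posterior sequence samples and
    ``mcmc_loglik`` the per-iteration data log-likelihood.
    """

    event_set: EventSet
    sequences: np.ndarray  # (C, N) int
    fractions: np.ndarray  # (C,)
    sigma: np.ndarray  # (B,) per-biomarker noise SD in w-score units
    log_likelihood: float = float("nan")
    fit_log: dict = field(default_factory=dict)
    mcmc_samples: list[np.ndarray] | None = None
    mcmc_loglik: np.ndarray | None = None

    @property
    def n_subtypes(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_events(self) -> int:
        return self.event_set.n_events

    def trajectories(self) -> np.ndarray:
        """Stacked expected-value matrices, shape (C, N+1, B)."""
        return np.stack([trajectory_matrix(self.event_set, s) for s in self.sequences])


@dataclass(frozen=True)
class FitConfig:
    """Tunable fitting schedule (all deterministic given ``seed``)."""

    n_restarts: int = 25  # greedy restarts for the single-sequence fit
    n_split_attempts: int = 5  # random bipartitions tried per split candidate
    n_split_restarts: int = 3  # greedy restarts when refitting split halves
    n_split_passes: int = 10  # greedy passes per split half-fit (rough inits suffice)
    em_tol: float = 1e-6  # stop EM when log-likelihood gain falls below this
    max_em_iter: int = 100
    max_greedy_passes: int = 30
    seed: int = 0


# ---------------------------------------------------------------------------
# likelihood


def _as_matrix(W) -> np.ndarray:
    W = np.asarray(getattr(W, "values", W), dtype=float)
    if W.ndim == 1:
        W = W[None, :]
    if not np.all(np.isfinite(W)):
        raise ValueError("w-score matrix contains non-finite values")
    return W


def stage_loglik_matrix(W: np.ndarray, E: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log-likelihood of each subject at each stage, shape (n, N+1).

    Uses the expansion sum_b ((w-E)/sigma)^2 = |w|^2 - 2 w.E + |E|^2 on the
    sigma-scaled data so the subject x stage grid is a single matrix product.
    """
    Ws = W / sigma
    Es = E / sigma
    const = -0.5 * W.shape[1] * _LOG2PI - float(np.sum(np.log(sigma)))
    D = (Ws**2).sum(axis=1)[:, None] - 2.0 * Ws @ Es.T + (Es**2).sum(axis=1)[None, :]
    return const - 0.5 * D


def stage_likelihood(w_row, event_set: EventSet, order, stage: int, sigma=None) -> float:
    """Density of one w-score row at one stage of one sequence."""
    if not 0 <= stage <= event_set.n_events:
        raise ValueError(f"stage {stage} outside 0..{event_set.n_events}")
    W = _as_matrix(w_row)
    sigma = _as_sigma(sigma, event_set.n_biomarkers)
    E = trajectory_matrix(event_set, np.asarray(order))
    return float(np.exp(stage_loglik_matrix(W, E[stage : stage + 1], sigma)[0, 0]))


def _as_sigma(sigma, B: int) -> np.ndarray:
    if sigma is None:
        return np.ones(B)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(B, float(sigma))
    if sigma.shape != (B,) or np.any(sigma <= 0):
        raise ConfigurationError("sigma must be positive, one value per biomarker")
    return sigma


def _subject_loglik_per_subtype(W: np.ndarray, model: SubtypeModel) -> np.ndarray:
    """log p(x_i | subtype c) marginal over the uniform stage prior, (n, C)."""
    N = model.n_events
    out = np.empty((W.shape[0], model.n_subtypes))
    for c, seq in enumerate(model.sequences):
        L = stage_loglik_matrix(W, trajectory_matrix(model.event_set, seq), model.sigma)
        out[:, c] = _logmeanexp(L, axis=1)
    return out


def _logmeanexp(L: np.ndarray, axis: int) -> np.ndarray:
    m = L.max(axis=axis)
    return m + np.log(np.exp(L - np.expand_dims(m, axis)).sum(axis=axis)) - np.log(L.shape[axis])


def data_log_likelihood(W, model: SubtypeModel) -> float:
    """Total log-likelihood of a w-score matrix under a fitted model."""
    W = _as_matrix(W)
    if W.shape[0] == 0:
        raise ValueError("empty w-score matrix")
    lc = _subject_loglik_per_subtype(W, model) + np.log(model.fractions)[None, :]
    m = lc.max(axis=1)
    return float(np.sum(m + np.log(np.exp(lc - m[:, None]).sum(axis=1))))


# ---------------------------------------------------------------------------
# greedy sequence optimization


class _SequenceOptimizer:
    """Weighted greedy event-relocation ascent for one sequence.

    The objective is sum_i weight_i * log-mean-exp_k L_ik, i.e. the
    responsibility-weighted marginal log-likelihood of the subjects under a
    single sequence with a uniform stage prior.
    """

    def __init__(self, event_set: EventSet, W: np.ndarray, sigma: np.ndarray):
        self.es = event_set
        self.sigma = sigma
        self.Ws = W / sigma
        self.ss = (self.Ws**2).sum(axis=1)
        self.const = -0.5 * W.shape[1] * _LOG2PI - float(np.sum(np.log(sigma)))
        self.n = W.shape[0]
        # compact per-biomarker layout for the numba kernels
        self._ev_bio = event_set.event_biomarker.astype(np.int64)
        nev = np.bincount(self._ev_bio, minlength=event_set.n_biomarkers)
        self._bio_nev = nev.astype(np.int64)
        self._bio_thr = np.zeros((event_set.n_biomarkers, int(nev.max())))
        for b in range(event_set.n_biomarkers):
            thr = event_set.event_threshold[event_set.events_of(b)]
            self._bio_thr[b, : thr.size] = thr  # ascending by enumeration
        self._zmax = event_set.z_max.astype(float)

    def trajectory(self, order: np.ndarray) -> np.ndarray:
        return build_trajectory(np.ascontiguousarray(order, dtype=np.int64), self._ev_bio,
                                self._bio_thr, self._bio_nev, self._zmax, self.es.n_biomarkers)

    def subject_loglik(self, order: np.ndarray) -> np.ndarray:
        E = self.trajectory(order) / self.sigma
        D = self.ss[:, None] - 2.0 * self.Ws @ E.T + (E**2).sum(axis=1)[None, :]
        return _logmeanexp(self.const - 0.5 * D, axis=1)

    def objective(self, order: np.ndarray, weights: np.ndarray) -> float:
        return float(weights @ self.subject_loglik(order))

    def _candidate_objectives(self, order: np.ndarray, event: int, weights: np.ndarray) -> np.ndarray:
        """Objective of moving ``event`` to every target position, shape (N,)."""
        rest = np.ascontiguousarray(order[order != event], dtype=np.int64)
        return reloc_objectives(rest, np.int64(event), self._ev_bio, self._bio_thr,
                                self._bio_nev, self._zmax, self.Ws, self.ss,
                                np.ascontiguousarray(weights, dtype=float),
                                self.const, self.sigma)

    def ascend(self, order: np.ndarray, weights: np.ndarray, rng: np.random.Generator,
               max_passes: int = 30) -> tuple[np.ndarray, float]:
        """Relocate events one at a time until no move improves the objective."""
        order = canonicalize_sequence(self.es, np.asarray(order))
        weights = np.asarray(weights, dtype=float)
        best = self.objective(order, weights)
        N = self.es.n_events
        for _ in range(max_passes):
            improved = False
            for event in rng.permutation(N):
                obj = self._candidate_objectives(order, int(event), weights)
                q = int(np.argmax(obj))  # ties: smallest index wins
                if obj[q] > best + 1e-10:
                    order = canonicalize_sequence(
                        self.es, np.insert(order[order != event], q, event))
                    best = float(obj[q])
                    improved = True
            if not improved:
                break
        return order, best


def _random_sequence(event_set: EventSet, rng: np.random.Generator) -> np.ndarray:
    return canonicalize_sequence(event_set, rng.permutation(event_set.n_events))


def _fit_single_sequence(opt: _SequenceOptimizer, weights: np.ndarray, n_restarts: int,
                         rng: np.random.Generator, max_passes: int) -> tuple[np.ndarray, float]:
    best_order, best_obj = None, -np.inf
    for _ in range(max(1, n_restarts)):
        order, obj = opt.ascend(_random_sequence(opt.es, rng), weights, rng, max_passes)
        if obj > best_obj:
            best_order, best_obj = order, obj
    return best_order, best_obj


# ---------------------------------------------------------------------------
# fitting


def fit(W, event_set: EventSet, n_subtypes: int = 1, *, sigma=None,
        config: FitConfig | None = None, base_model: SubtypeModel | None = None) -> SubtypeModel:
    """Fit a model with ``n_subtypes`` subtypes by hierarchical EM.

    For one subtype this is greedy event-relocation ascent from
    ``config.n_restarts`` random sequences.  For C > 1 the fitted (C-1)-model
    (refit internally unless supplied as ``base_model``) is used for
    initialization: each of its subtypes is split by a random bipartition of
    its hard-assigned subjects, the halves are refit as single sequences, the
    best initialization is kept, and EM then alternates responsibilities,
    fraction updates and responsibility-weighted sequence re-optimization
    until the log-likelihood gain drops below ``config.em_tol``.
    """
    models = fit_hierarchy(W, event_set, n_subtypes, sigma=sigma, config=config,
                           base_model=base_model)
    return models[n_subtypes]


def fit_hierarchy(W, event_set: EventSet, max_subtypes: int, *, sigma=None,
                  config: FitConfig | None = None,
                  base_model: SubtypeModel | None = None) -> dict[int, SubtypeModel]:
    """Fit models for every C up to ``max_subtypes``; returns {C: model}."""
    cfg = config or FitConfig()
    W = _as_matrix(W)
    if max_subtypes < 1:
        raise ConfigurationError("n_subtypes must be >= 1")
    if max_subtypes > W.shape[0]:
        raise ConfigurationError(f"n_subtypes={max_subtypes} exceeds the {W.shape[0]} subjects")
    sig = _as_sigma(sigma, event_set.n_biomarkers)
    opt = _SequenceOptimizer(event_set, W, sig)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 0xF17]))
    ones = np.ones(W.shape[0])

    models: dict[int, SubtypeModel] = {}
    start_c = 1
    if base_model is not None:
        if base_model.event_set != event_set:
            raise ConfigurationError("base_model has a different event set")
        models[base_model.n_subtypes] = base_model
        start_c = base_model.n_subtypes + 1

    for C in range(start_c, max_subtypes + 1):
        if C == 1:
            order, obj = _fit_single_sequence(opt, ones, cfg.n_restarts, rng, cfg.max_greedy_passes)
            model = SubtypeModel(event_set, order[None, :], np.array([1.0]), sig,
                                 log_likelihood=obj,
                                 fit_log={"n_subtypes": 1, "n_restarts": cfg.n_restarts,
                                          "seed": cfg.seed, "em_loglik": [obj]})
        else:
            model = _fit_split_em(opt, models[C - 1], cfg, rng)
        models[C] = model
    return models


def _pattern_bipartition(W_members: np.ndarray, members: np.ndarray,
                         rng: np.random.Generator):
    """Split subjects into two groups by 2-means on unit-normalized rows."""
    norms = np.linalg.norm(W_members, axis=1)
    ok = norms > 1e-9
    if ok.sum() < 4:
        return None, None
    U = W_members[ok] / norms[ok, None]
    from scipy.cluster.vq import kmeans2

    _, labels = kmeans2(U, 2, minit="++", seed=int(rng.integers(2**31)))
    a = members[ok][labels == 0]
    b = members[ok][labels == 1]
    rest = members[~ok]
    if rest.size:  # near-zero rows carry no pattern; spread them evenly
        a = np.concatenate([a, rest[::2]])
        b = np.concatenate([b, rest[1::2]])
    if min(a.size, b.size) < 2:
        return None, None
    return a, b


def _responsibilities(opt: _SequenceOptimizer, sequences, fractions) -> tuple[np.ndarray, float]:
    lc = np.stack([opt.subject_loglik(s) for s in sequences], axis=1) + np.log(fractions)[None, :]
    m = lc.max(axis=1)
    ll = float(np.sum(m + np.log(np.exp(lc - m[:, None]).sum(axis=1))))
    R = np.exp(lc - lc.max(axis=1, keepdims=True))
    R /= R.sum(axis=1, keepdims=True)
    return R, ll


def _fit_split_em(opt: _SequenceOptimizer, base: SubtypeModel, cfg: FitConfig,
                  rng: np.random.Generator) -> SubtypeModel:
    es, n = opt.es, opt.n
    C = base.n_subtypes + 1
    R, _ = _responsibilities(opt, base.sequences, base.fractions)
    hard = R.argmax(axis=1)

    inits = []  # (init ll, sequences, fractions)
    for c in range(base.n_subtypes):
        members = np.flatnonzero(hard == c)
        if members.size < 4:
            continue
        for attempt in range(max(1, cfg.n_split_attempts)):
            a = None
            if attempt == 0:
                # pattern-based bipartition: 2-means on unit-normalized rows
                # separates co-clustered progression patterns regardless of
                # severity, a far better EM basin than a random split
                a, b = _pattern_bipartition(opt.Ws[members] * opt.sigma, members, rng)
            if a is None:
                half = rng.permutation(members)
                a, b = half[: members.size // 2], half[members.size // 2 :]
            seqs = []
            for idx in (a, b):
                sub_opt = _SequenceOptimizer(es, opt.Ws[idx] * opt.sigma, opt.sigma)
                seq, _ = _fit_single_sequence(sub_opt, np.ones(idx.size), cfg.n_split_restarts,
                                              rng, cfg.n_split_passes)
                seqs.append(seq)
            cand_seqs = np.vstack([np.delete(base.sequences, c, axis=0), seqs[0][None], seqs[1][None]])
            frac = np.append(np.delete(base.fractions, c),
                             [base.fractions[c] / 2, base.fractions[c] / 2])
            _, ll = _responsibilities(opt, cand_seqs, frac)
            inits.append((ll, cand_seqs, frac))
    if not inits:
        raise ConfigurationError(f"no subtype of the {base.n_subtypes}-subtype model is large enough to split")

    # run EM from the two most promising initializations and keep the better
    # optimum: a single EM run from the best init occasionally lands in a
    # merged-subtype basin, and that local optimum is what model comparison
    # ultimately sees
    inits.sort(key=lambda t: -t[0])
    best_model, best_final = None, -np.inf
    for init_ll, sequences, fractions in inits[:2]:
        sequences = np.array(sequences)
        fractions = np.array(fractions)
        em_ll: list[float] = []
        ll_prev = -np.inf
        for _ in range(cfg.max_em_iter):
            R, ll = _responsibilities(opt, sequences, fractions)
            em_ll.append(ll)
            if ll - ll_prev < cfg.em_tol and len(em_ll) > 1:
                break
            ll_prev = ll
            fractions = np.maximum(R.mean(axis=0), 1e-12)
            fractions = fractions / fractions.sum()
            for c in range(C):
                # negligible responsibilities are zeroed so the kernel skips
                # those subjects; the objective change is < 1e-8 per subject
                w = np.where(R[:, c] < 1e-10, 0.0, R[:, c])
                sequences[c], _ = opt.ascend(sequences[c], w, rng, max_passes=1)
        # polish: run the final M-step to convergence at the last
        # responsibilities (the EM inequality keeps the mixture ll monotone)
        R, _ = _responsibilities(opt, sequences, fractions)
        for c in range(C):
            w = np.where(R[:, c] < 1e-10, 0.0, R[:, c])
            sequences[c], _ = opt.ascend(sequences[c], w, rng, max_passes=cfg.max_greedy_passes)
        R, ll = _responsibilities(opt, sequences, fractions)
        em_ll.append(ll)
        if ll > best_final:
            best_final = ll
            best_model = SubtypeModel(opt.es, np.asarray(sequences), fractions, opt.sigma,
                                      log_likelihood=ll,
                                      fit_log={"n_subtypes": C, "seed": cfg.seed,
                                               "em_loglik": em_ll, "init_loglik": init_ll})
    return best_model


# ---------------------------------------------------------------------------
# MCMC


def mcmc(W, model: SubtypeModel, n_iter: int = 10_000, seed: int = 0) -> SubtypeModel:
    """Metropolis sampling over sequence space, started at the fitted model.

    Each iteration picks one subtype, relocates one randomly chosen event to a
    uniformly random position (re-sorting that biomarker's thresholds into
    ascending order), and accepts with min(1, likelihood ratio).  All
    ``n_iter`` samples are retained: the chain starts at the EM/greedy
    optimum, so no burn-in period is discarded.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    W = _as_matrix(W)
    es, N, C = model.event_set, model.n_events, model.n_subtypes
    opt = _SequenceOptimizer(es, W, model.sigma)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x3C3C]))

    sequences = [np.array(s) for s in model.sequences]
    lc = np.stack([opt.subject_loglik(s) for s in sequences], axis=1)
    logf = np.log(model.fractions)

    def total_ll(lc_):
        x = lc_ + logf[None, :]
        m = x.max(axis=1)
        return float(np.sum(m + np.log(np.exp(x - m[:, None]).sum(axis=1))))

    ll = total_ll(lc)
    samples = [np.empty((n_iter, N), dtype=np.int16) for _ in range(C)]
    ll_trace = np.empty(n_iter)
    n_accept = 0
    for it in range(n_iter):
        c = int(rng.integers(C))
        event = int(rng.integers(N))
        q = int(rng.integers(N))
        cand = np.insert(sequences[c][sequences[c] != event], q, event)
        cand = canonicalize_sequence(es, cand)
        lc_cand = opt.subject_loglik(cand)
        lc_new = lc.copy()
        lc_new[:, c] = lc_cand
        ll_new = total_ll(lc_new)
        if ll_new >= ll or np.log(rng.uniform()) < ll_new - ll:
            sequences[c], lc, ll = cand, lc_new, ll_new
            n_accept += 1
        for cc in range(C):
            samples[cc][it] = sequences[cc]
        ll_trace[it] = ll

    out = replace(model)
    out.mcmc_samples = samples
    out.mcmc_loglik = ll_trace
    out.fit_log = dict(model.fit_log, mcmc_iters=n_iter, mcmc_seed=seed,
                       mcmc_acceptance=n_accept / n_iter)
    return out


# ---------------------------------------------------------------------------
# cross-validated model selection


@dataclass
class CVICResult:
    """Cross-validation information criterion over candidate subtype counts."""

    candidates: tuple[int, ...]
    fold_loglik: np.ndarray  # (n_folds, n_candidates) held-out log-likelihood
    cvic: np.ndarray  # (n_candidates,)
    selected: int
    n_folds: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "candidates": list(self.candidates),
            "cvic": [float(x) for x in self.cvic],
            "fold_loglik": self.fold_loglik.tolist(),
            "selected": int(self.selected),
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def cross_validate(W, event_set: EventSet, candidate_Cs=(1, 2, 3, 4, 5), n_folds: int = 10,
                   *, sigma=None, config: FitConfig | None = None, seed: int = 0) -> CVICResult:
    """Select the number of subtypes by CVIC.

    Subjects are split into ``n_folds`` random folds (fixed seed); for every
    fold and candidate C a model hierarchy is fitted on the training folds
    (point-estimate sequences) and the held-out subjects' -2 log-likelihood is
    accumulated; CVIC(C) sums over folds and the argmin C is selected
    (smallest C wins ties).
    """
    candidates = tuple(int(c) for c in candidate_Cs)
    if not candidates:
        raise ConfigurationError("candidate_Cs must be non-empty")
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    W = _as_matrix(W)
    n = W.shape[0]
    if n < n_folds:
        raise ConfigurationError("fewer subjects than folds")
    cfg = config or FitConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xCF1D]))
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    if any(f.size == 0 for f in folds):
        raise ConfigurationError("a fold has zero test subjects")

    fold_ll = np.empty((n_folds, len(candidates)))
    for i, test_idx in enumerate(folds):
        train = np.delete(np.arange(n), test_idx)
        models = fit_hierarchy(W[train], event_set, max(candidates), sigma=sigma,
                               config=replace(cfg, seed=cfg.seed + 1000 * i + 1))
        for j, C in enumerate(candidates):
            fold_ll[i, j] = data_log_likelihood(W[test_idx], models[C])
    cvic = (-2.0 * fold_ll).sum(axis=0)
    selected = candidates[int(np.argmin(cvic))]
    return CVICResult(candidates, fold_ll, cvic, selected, n_folds, seed)
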