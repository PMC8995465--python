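"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Each document d mixes K topics with proportions theta_d ~ Dirichlet(alpha);
each topic k is a distribution phi_k over the V vocabulary words,
phi_k ~ Dirichlet(beta).  Collapsed Gibbs sampling integrates theta and phi
out analytically and resamples each token's topic label z_i from

    p(z_i = k | z_-i, w)  ∝  (n_kw + beta) / (n_k + V*beta) * (n_dk + alpha),

where the counts exclude token i.  Point estimates of phi and theta are
posterior means computed from counts averaged over thinned post-burn-in
sweeps, which reduces variance while staying seed-deterministic.

The per-token sweep is JIT-compiled (numba) with an explicit 64-bit linear
congruential generator so that identical seed and input give bit-identical
assignments on any machine.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numba
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .text_prep import BowCorpus

logger = logging.getLogger(__name__)

__all__ = [
    "LdaConfig",
    "LdaModel",
    "fit",
    "log_joint",
    "perplexity",
    "select_k",
    "top_terms",
    "token_streams",
]


@dataclass(frozen=True)
class LdaConfig:
    """Sampler settings.

    ``alpha`` defaults to 50/K and ``beta`` to 0.01, the usual heuristics for
    abstract-length documents; 1,000 sweeps with 500 burn-in and thinning of
    10 are comfortable for corpora of a few thousand short documents.
    """

    K: int = 50
    alpha: Optional[float] = None
    beta: float = 0.01
    n_iterations: int = 1000
    burn_in: int = 500
    sample_every: int = 10
    n_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.resolved_alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if not self.n_iterations > self.burn_in >= 0:
            raise ValueError("need n_iterations > burn_in >= 0")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")

    @property
    def resolved_alpha(self) -> float:
        return 50.0 / self.K if self.alpha is None else self.alpha


@dataclass
class LdaModel:
    """Fitted model: row-stochastic phi (K x V) and theta (D x K), final
    token assignments ``z`` and the count tables consistent with them."""

    phi: np.ndarray
    theta: np.ndarray
    z: np.ndarray
    n_kw: np.ndarray
    n_dk: np.ndarray
    config: LdaConfig
    terms: list[str] = field(default_factory=list)
    doc_ids: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.phi.shape[0]

    @property
    def V(self) -> int:
        return self.phi.shape[1]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            outdir / "model.npz",
            phi=self.phi,
            theta=self.theta,
            z=self.z,
            n_kw=self.n_kw,
            n_dk=self.n_dk,
        )
        with open(outdir / "config.json", "w") as fh:
            json.dump(
                {
                    "K": self.config.K,
                    "alpha": self.config.alpha,
                    "beta": self.config.beta,
                    "n_iterations": self.config.n_iterations,
                    "burn_in": self.config.burn_in,
                    "sample_every": self.config.sample_every,
                    "n_restarts": self.config.n_restarts,
                    "seed": self.config.seed,
                    "terms": self.terms,
                    "doc_ids": self.doc_ids,
                },
                fh,
            )
        with open(outdir / "top_terms.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["topic", "rank", "term", "probability"])
            if self.terms:
                for k in range(self.K):
                    for rank, (term, prob) in enumerate(top_terms(self, k, 10)):
                        writer.writerow([k, rank, term, f"{prob:.6g}"])

    @classmethod
    def load(cls, outdir) -> "LdaModel":
        outdir = Path(outdir)
        arrays = np.load(outdir / "model.npz")
        with open(outdir / "config.json") as fh:
            meta = json.load(fh)
        terms = meta.pop("terms")
        doc_ids = meta.pop("doc_ids")
        return cls(
            phi=arrays["phi"],
            theta=arrays["theta"],
            z=arrays["z"],
            n_kw=arrays["n_kw"],
            n_dk=arrays["n_dk"],
            config=LdaConfig(**meta),
            terms=terms,
            doc_ids=doc_ids,
        )


# ---------------------------------------------------------------------------
# Token streams: deterministic flattening of a bag-of-words corpus
# ---------------------------------------------------------------------------

def token_streams(corpus: BowCorpus) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a BowCorpus to aligned (doc index, word index) token arrays.

    Tokens are emitted in document order, within a document by ascending word
    index, repeated by count — the canonical order used by the sampler and by
    :func:`log_joint`, so assignment vectors are comparable between the two.
    """
    doc_of: list[int] = []
    word_of: list[int] = []
    for d, doc in enumerate(corpus.docs):
        for w in sorted(doc):
            c = doc[w]
            doc_of.extend([d] * c)
            word_of.extend([w] * c)
    return (
        np.asarray(doc_of, dtype=np.int32),
        np.asarray(word_of, dtype=np.int32),
    )


# ---------------------------------------------------------------------------
# JIT kernels (explicit LCG for cross-platform seed determinism)
# ---------------------------------------------------------------------------

_U64_MULT = np.uint64(6364136223846793005)
_U64_INC = np.uint64(1442695040888963407)
_U64_SHIFT = np.uint64(11)
_INV_2_53 = 1.0 / 9007199254740992.0


@numba.njit(inline="always")
def _next_uniform(state):
    s = state[0] * _U64_MULT + _U64_INC
    state[0] = s
    return np.float64(s >> _U64_SHIFT) * _INV_2_53


def _init_rng_state(seed: int) -> np.ndarray:
    # splitmix64 finalizer: nearby integer seeds give unrelated LCG streams
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed & 0x7FFFFFFF)
    state += np.uint64(0x9E3779B97F4A7C15)
    state ^= state >> np.uint64(30)
    state *= np.uint64(0xBF58476D1CE4E5B9)
    state ^= state >> np.uint64(27)
    state *= np.uint64(0x94D049BB133111EB)
    state ^= state >> np.uint64(31)
    return state


@numba.njit
def _init_assignments(doc_of, word_of, z, n_kw, n_dk, n_k, state):
    K = n_kw.shape[0]
    for i in range(doc_of.shape[0]):
        k = int(_next_uniform(state) * K)
        if k >= K:
            k = K - 1
        z[i] = k
        n_kw[k, word_of[i]] += 1
        n_dk[doc_of[i], k] += 1
        n_k[k] += 1


@numba.njit
def _gibbs_sweeps(doc_of, word_of, z, n_kw, n_dk, n_k, alpha, beta, n_sweeps, state):
    K, V = n_kw.shape
    vbeta = V * beta
    cum = np.empty(K, np.float64)
    for _ in range(n_sweeps):
        for i in range(doc_of.shape[0]):
            d = doc_of[i]
            w = word_of[i]
            k = z[i]
            n_kw[k, w] -= 1
            n_dk[d, k] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (
                    (n_kw[kk, w] + beta)
                    / (n_k[kk] + vbeta)
                    * (n_dk[d, kk] + alpha)
                )
                cum[kk] = total
            u = _next_uniform(state) * total
            k = 0
            while k < K - 1 and cum[k] < u:
                k += 1
            z[i] = k
            n_kw[k, w] += 1
            n_dk[d, k] += 1
            n_k[k] += 1


@numba.njit
def _fold_in_sweeps(doc_of, word_of, z, phi, n_dk, alpha, n_sweeps, state):
    K = phi.shape[0]
    cum = np.empty(K, np.float64)
    for _ in range(n_sweeps):
        for i in range(doc_of.shape[0]):
            d = doc_of[i]
            w = word_of[i]
            n_dk[d, z[i]] -= 1
            total = 0.0
            for kk in range(K):
                total += phi[kk, w] * (n_dk[d, kk] + alpha)
                cum[kk] = total
            u = _next_uniform(state) * total
            k = 0
            while k < K - 1 and cum[k] < u:
                k += 1
            z[i] = k
            n_dk[d, k] += 1


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit(corpus: BowCorpus, config: LdaConfig) -> LdaModel:
    """Run the collapsed Gibbs sampler on a bag-of-words corpus.

    phi and theta are posterior means from counts averaged over every
    ``sample_every``-th post-burn-in sweep.  With ``n_restarts > 1``
    independent chains are run from seeds ``seed, seed+1, ...`` and the one
    whose final state has the highest collapsed log-joint is kept — the
    standard guard against a chain stalling in a topic merge/split mode.
    Identical seed and input give an identical model.  Raises on an empty
    corpus; warns when V < K.
    """
    if config.n_restarts > 1:
        best_model, best_lp = None, -np.inf
        single = replace(config, n_restarts=1)
        for i in range(config.n_restarts):
            chain = replace(single, seed=(config.seed + i) % 2**31)
            model = fit(corpus, chain)
            lp = log_joint(corpus, model.z, chain)
            if lp > best_lp:
                best_model, best_lp = model, lp
        assert best_model is not None
        best_model.config = config
        return best_model
    if len(corpus) == 0:
        raise ValueError("cannot fit LDA on an empty corpus")
    K = config.K
    V = len(corpus.vocab)
    D = len(corpus)
    if V < K:
        warnings.warn(
            f"vocabulary size {V} < K={K}; topics cannot all be distinct",
            stacklevel=2,
        )
    alpha = config.resolved_alpha
    beta = config.beta
    doc_of, word_of = token_streams(corpus)
    n = doc_of.shape[0]
    if n == 0:
        raise ValueError("corpus has no in-vocabulary tokens")

    z = np.zeros(n, dtype=np.int32)
    n_kw = np.zeros((K, V), dtype=np.int32)
    n_dk = np.zeros((D, K), dtype=np.int32)
    n_k = np.zeros(K, dtype=np.int32)
    state = _init_rng_state(config.seed)
    _init_assignments(doc_of, word_of, z, n_kw, n_dk, n_k, state)

    _gibbs_sweeps(
        doc_of, word_of, z, n_kw, n_dk, n_k, alpha, beta, config.burn_in, state
    )
    post = config.n_iterations - config.burn_in
    acc_kw = np.zeros((K, V), dtype=np.float64)
    acc_dk = np.zeros((D, K), dtype=np.float64)
    n_samples = 0
    remaining = post
    while remaining > 0:
        step = min(config.sample_every, remaining)
        _gibbs_sweeps(
            doc_of, word_of, z, n_kw, n_dk, n_k, alpha, beta, step, state
        )
        remaining -= step
        acc_kw += n_kw
        acc_dk += n_dk
        n_samples += 1

    total = n_kw.sum()
    if total != n or n_dk.sum() != n:
        raise AssertionError("count conservation violated after sampling")
    if not np.isfinite(acc_kw).all():
        raise FloatingPointError("non-finite values in accumulated counts")

    acc_kw /= n_samples
    acc_dk /= n_samples
    phi = (acc_kw + beta) / (acc_kw.sum(axis=1, keepdims=True) + V * beta)
    theta = (acc_dk + alpha) / (acc_dk.sum(axis=1, keepdims=True) + K * alpha)
    return LdaModel(
        phi=phi,
        theta=theta,
        z=z,
        n_kw=n_kw,
        n_dk=n_dk,
        config=config,
        terms=list(corpus.vocab.terms),
        doc_ids=list(corpus.doc_ids),
    )


# ---------------------------------------------------------------------------
# Collapsed joint (enumeration oracle support)
# ---------------------------------------------------------------------------

def log_joint(corpus: BowCorpus, z: Sequence[int], config: LdaConfig) -> float:
    """Log of the collapsed joint p(w, z) under symmetric Dirichlet priors.

    ``z`` assigns a topic to every token in the canonical
    :func:`token_streams` order.  Exact up to an additive constant shared by
    all assignment vectors, which is all an enumeration oracle needs.
    """
    doc_of, word_of = token_streams(corpus)
    z = np.asarray(z, dtype=np.int64)
    if z.shape[0] != doc_of.shape[0]:
        raise ValueError(
            f"assignment length {z.shape[0]} != token count {doc_of.shape[0]}"
        )
    K = config.K
    V = len(corpus.vocab)
    D = len(corpus)
    if z.min(initial=0) < 0 or z.max(initial=0) >= K:
        raise ValueError("topic assignment out of range")
    alpha = config.resolved_alpha
    beta = config.beta
    n_dk = np.zeros((D, K))
    n_kw = np.zeros((K, V))
    np.add.at(n_dk, (doc_of, z), 1)
    np.add.at(n_kw, (z, word_of), 1)
    n_d = n_dk.sum(axis=1)
    n_k = n_kw.sum(axis=1)
    lp = 0.0
    lp += np.sum(gammaln(n_dk + alpha)) - np.sum(gammaln(n_d + K * alpha))
    lp += D * (gammaln(K * alpha) - K * gammaln(alpha))
    lp += np.sum(gammaln(n_kw + beta)) - np.sum(gammaln(n_k + V * beta))
    lp += K * (gammaln(V * beta) - V * gammaln(beta))
    return float(lp)


# ---------------------------------------------------------------------------
# Perplexity and topic-number selection
# ---------------------------------------------------------------------------

def _perplexity_from(phi: np.ndarray, theta: np.ndarray, docs) -> float:
    log_lik = 0.0
    n_tokens = 0
    for d, doc in enumerate(docs):
        if not doc:
            continue
        words = np.fromiter(doc.keys(), dtype=np.int64, count=len(doc))
        counts = np.fromiter(doc.values(), dtype=np.float64, count=len(doc))
        mix = theta[d] @ phi[:, words]
        if np.any(mix <= 0):
            raise ValueError(
                "zero-probability token; use beta > 0 for smoothed estimates"
            )
        log_lik += float(counts @ np.log(mix))
        n_tokens += int(counts.sum())
    if n_tokens == 0:
        raise ValueError("corpus has no in-vocabulary tokens")
    return float(np.exp(-log_lik / n_tokens))


def perplexity(
    model: LdaModel, corpus: BowCorpus, theta: Optional[np.ndarray] = None
) -> float:
    """exp(-mean per-token log-likelihood) under the theta'phi mixture.

    Uses the model's own theta by default (training perplexity); pass a
    folded-in ``theta`` to score held-out documents.  A uniform phi gives
    exactly V for any theta; lower is better.
    """
    theta = model.theta if theta is None else theta
    if len(corpus) != theta.shape[0]:
        raise ValueError("theta rows must match corpus documents")
    return _perplexity_from(model.phi, theta, corpus.docs)


def fold_in(
    model: LdaModel, corpus: BowCorpus, n_sweeps: int = 50, seed: int = 0
) -> np.ndarray:
    """Estimate theta for unseen documents with phi held fixed."""
    doc_of, word_of = token_streams(corpus)
    K = model.K
    D = len(corpus)
    alpha = model.config.resolved_alpha
    n_dk = np.zeros((D, K), dtype=np.int32)
    z = np.zeros(doc_of.shape[0], dtype=np.int32)
    n_k = np.zeros(K, dtype=np.int32)
    n_kw = np.zeros((K, model.V), dtype=np.int32)  # unused bookkeeping
    state = _init_rng_state(seed)
    _init_assignments(doc_of, word_of, z, n_kw, n_dk, n_k, state)
    _fold_in_sweeps(
        doc_of, word_of, z, model.phi, n_dk, alpha, n_sweeps, state
    )
    return (n_dk + alpha) / (n_dk.sum(axis=1, keepdims=True) + K * alpha)


def select_k(
    corpus: BowCorpus,
    candidate_Ks: Sequence[int],
    config_template: LdaConfig,
) -> pd.DataFrame:
    """Held-out perplexity for each candidate topic number.

    Splits documents 90/10 by the template seed, fits on the 90% and scores
    the 10% via fold-in.  Returns a table sorted by K; repeated calls with
    identical inputs give identical tables.
    """
    if not candidate_Ks:
        raise ValueError("candidate_Ks must be nonempty")
    D = len(corpus)
    if D < 2:
        raise ValueError("corpus too small for a train/held-out split")
    rng = np.random.default_rng(config_template.seed)
    order = rng.permutation(D)
    n_held = max(1, D // 10)
    held_idx = set(order[:n_held].tolist())

    def subset(indices):
        return BowCorpus(
            docs=[corpus.docs[i] for i in indices],
            doc_ids=[corpus.doc_ids[i] for i in indices],
            vocab=corpus.vocab,
        )

    train = subset([i for i in range(D) if i not in held_idx])
    held = subset([i for i in range(D) if i in held_idx])
    rows = []
    for K in sorted(candidate_Ks):
        config = replace(config_template, K=K)
        model = fit(train, config)
        theta_held = fold_in(model, held, seed=config.seed)
        pp = _perplexity_from(model.phi, theta_held, held.docs)
        logger.info("select_k: K=%d held-out perplexity %.2f", K, pp)
        rows.append({"K": K, "heldout_perplexity": pp})
    return pd.DataFrame(rows)


def matched_tv_distance(phi_true: np.ndarray, phi_est: np.ndarray) -> float:
    """Mean total-variation distance between true and estimated topic rows
    after greedy matching.

    Topics are only identified up to label permutation, so each true row is
    greedily paired with the closest unused estimated row; the mean TV
    distance over pairs scores recovery (0 = perfect, 1 = disjoint support).
    """
    phi_true = np.asarray(phi_true, dtype=float)
    phi_est = np.asarray(phi_est, dtype=float)
    if phi_true.shape != phi_est.shape:
        raise ValueError("phi matrices must have identical shape")
    K = phi_true.shape[0]
    tv = 0.5 * np.abs(phi_true[:, None, :] - phi_est[None, :, :]).sum(axis=2)
    # greedy: repeatedly take the global minimum over unused rows/cols
    used_rows: set[int] = set()
    used_cols: set[int] = set()
    total = 0.0
    for _ in range(K):
        best_val, best_ij = np.inf, (0, 0)
        for i in range(K):
            if i in used_rows:
                continue
            for j in range(K):
                if j in used_cols:
                    continue
                if tv[i, j] < best_val:
                    best_val, best_ij = tv[i, j], (i, j)
        used_rows.add(best_ij[0])
        used_cols.add(best_ij[1])
        total += best_val
    return total / K


def top_terms(model: LdaModel, topic: int, n: int) -> list[tuple[str, float]]:
    """The n highest-probability terms of a topic, ties broken alphabetically."""
    if not 0 <= topic < model.K:
        raise ValueError(f"topic {topic} out of range [0, {model.K})")
    if not model.terms:
        raise ValueError("model carries no vocabulary terms")
    row = model.phi[topic]
    order = sorted(range(model.V), key=lambda w: (-row[w], model.terms[w]))
    return [(model.terms[w], float(row[w])) for w in order[:n]]
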