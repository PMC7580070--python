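"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Each article is a Dirichlet-drawn mixture over ``k`` topics and each topic a
Dirichlet-drawn distribution over the vocabulary.  The sampler integrates out
both Dirichlet layers and resamples token-topic assignments from their
collapsed conditionals; after the final sweep the smoothed count estimates

    phi[k, v]  = (n_kv + beta)  / (n_k + V * beta)
    p_ia[d, k] = (n_dk + alpha_k) / (n_d + sum(alpha))

give the topic-word and article-topic probabilities.  Dirichlet
hyperparameters (asymmetric alpha, scalar beta) are re-estimated every
``optimize_interval`` sweeps by Minka's fixed-point update; set the interval
to 0 to keep them fixed.

Estimates come from the final sampler state (a single draw), which is all the
downstream discretisation step needs.  Any external fitter producing the same
``TopicModelFit`` contract (row-stochastic phi and p_ia, strictly positive
entries) can be plugged in downstream via :meth:`TopicModelFit.from_matrices`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, psi

from .preprocess import DocTermMatrix


@dataclass
class TopicModelParams:
    """Sampler settings.

    ``alpha`` and ``beta`` default to the dispersions used for large clinical
    corpora (1/300 and 1/100); ``k`` defaults to a desk-scale 20 topics (the
    full-scale analysis uses 400, which is a configuration choice, not a test
    target).
    """

    k: int = 20
    alpha: float = 1.0 / 300.0
    beta: float = 1.0 / 100.0
    n_sweeps: int = 500
    optimize_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.optimize_interval < 0:
            raise ValueError("optimize_interval must be >= 0 (0 = fixed)")


@dataclass
class TopicModelFit:
    """Fitted topic model: row-stochastic phi (k x V) and p_ia (D x k)."""

    phi: np.ndarray
    p_ia: np.ndarray
    loglik_trace: np.ndarray
    params: TopicModelParams | None
    terms: list[str]
    row_ids: list[str]
    alpha: np.ndarray = field(default=None)  # per-topic, after optimisation
    beta: float = 0.0

    @classmethod
    def from_matrices(cls, phi, p_ia, terms, row_ids) -> "TopicModelFit":
        """Wrap matrices from any fitter that honours the contract."""
        phi = np.asarray(phi, dtype=float)
        p_ia = np.asarray(p_ia, dtype=float)
        if not np.allclose(phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1")
        if not np.allclose(p_ia.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("p_ia rows must sum to 1")
        return cls(
            phi=phi,
            p_ia=p_ia,
            loglik_trace=np.array([]),
            params=None,
            terms=list(terms),
            row_ids=list(row_ids),
        )

    def p_ia_frame(self):
        import pandas as pd

        return pd.DataFrame(self.p_ia, index=self.row_ids)

    def save(self, prefix: str) -> None:
        np.savez_compressed(
            f"{prefix}.npz",
            phi=self.phi,
            p_ia=self.p_ia,
            loglik_trace=self.loglik_trace,
            alpha=self.alpha if self.alpha is not None else np.array([]),
            beta=self.beta,
        )
        self.p_ia_frame().to_csv(f"{prefix}.p_ia.csv")


def _joint_loglik(n_kv, n_dk, n_k, n_d, alpha, beta) -> float:
    k, V = n_kv.shape
    a0 = alpha.sum()
    lw = k * (gammaln(V * beta) - V * gammaln(beta))
    lw += gammaln(n_kv + beta).sum() - gammaln(n_k + V * beta).sum()
    lz = len(n_d) * (gammaln(a0) - gammaln(alpha).sum())
    lz += gammaln(n_dk + alpha).sum() - gammaln(n_d + a0).sum()
    return float(lw + lz)


def _optimize_alpha(alpha, n_dk, n_d, n_iter=5) -> np.ndarray:
    D = n_dk.shape[0]
    for _ in range(n_iter):
        a0 = alpha.sum()
        num = psi(n_dk + alpha).sum(axis=0) - D * psi(alpha)
        den = psi(n_d + a0).sum() - D * psi(a0)
        if den <= 0:
            break
        alpha = np.clip(alpha * num / den, 1e-8, None)
    return alpha


def _optimize_beta(beta, n_kv, n_k, n_iter=5) -> float:
    k, V = n_kv.shape
    for _ in range(n_iter):
        num = psi(n_kv + beta).sum() - k * V * psi(beta)
        den = V * (psi(n_k + V * beta).sum() - k * psi(V * beta))
        if den <= 0:
            break
        beta = float(np.clip(beta * num / den, 1e-8, None))
    return beta


def fit_lda(dtm: DocTermMatrix, params: TopicModelParams) -> TopicModelFit:
    """Fit LDA to a document-term matrix by collapsed Gibbs sampling.

    Deterministic given ``params.seed``: the token visit order (document
    order, ascending term index within a document) and the sampler's random
    stream are both fixed, so two runs with the same inputs produce identical
    assignment trajectories.

    Raises ValueError naming the row for all-zero documents; warns when ``k``
    exceeds the number of distinct terms.
    """
    D, V = dtm.shape
    if D == 0 or dtm.counts.nnz == 0:
        raise ValueError("document-term matrix is empty")
    row_sums = dtm.row_token_counts()
    zero = np.where(row_sums == 0)[0]
    if zero.size:
        raise ValueError(
            f"all-zero document rows: {[dtm.row_ids[i] for i in zero[:5]]}"
        )
    k = params.k
    if k > V:
        warnings.warn(
            f"k={k} exceeds the number of distinct terms ({V})", stacklevel=2
        )

    rng = np.random.default_rng(params.seed)
    csr = dtm.counts.tocsr()

    # Expand each document into its token word-id sequence (deterministic order).
    doc_words: list[np.ndarray] = []
    for d in range(D):
        row = csr.getrow(d)
        doc_words.append(np.repeat(row.indices, row.data).astype(np.int64))

    alpha = np.full(k, float(params.alpha))
    beta = float(params.beta)

    n_dk = np.zeros((D, k), dtype=np.int64)
    n_kv = np.zeros((k, V), dtype=np.int64)
    n_k = np.zeros(k, dtype=np.int64)
    n_d = row_sums.astype(np.int64)

    assignments: list[np.ndarray] = []
    for d, words in enumerate(doc_words):
        z = rng.integers(0, k, size=words.size)
        assignments.append(z)
        np.add.at(n_dk[d], z, 1)
        np.add.at(n_kv, (z, words), 1)
        np.add.at(n_k, z, 1)

    loglik = np.empty(params.n_sweeps, dtype=float)
    for sweep in range(params.n_sweeps):
        for d, words in enumerate(doc_words):
            z = assignments[d]
            ndk_d = n_dk[d]
            for i in range(words.size):
                w = words[i]
                t = z[i]
                ndk_d[t] -= 1
                n_kv[t, w] -= 1
                n_k[t] -= 1
                p = (n_kv[:, w] + beta) / (n_k + V * beta) * (ndk_d + alpha)
                cum = np.cumsum(p)
                t_new = int(np.searchsorted(cum, rng.random() * cum[-1]))
                if t_new >= k:  # guard against fp edge at the top of the cdf
                    t_new = k - 1
                z[i] = t_new
                ndk_d[t_new] += 1
                n_kv[t_new, w] += 1
                n_k[t_new] += 1
        if (
            params.optimize_interval > 0
            and (sweep + 1) % params.optimize_interval == 0
        ):
            alpha = _optimize_alpha(alpha, n_dk, n_d)
            beta = _optimize_beta(beta, n_kv, n_k)
        loglik[sweep] = _joint_loglik(n_kv, n_dk, n_k, n_d, alpha, beta)

    phi = (n_kv + beta) / (n_k + V * beta)[:, None]
    p_ia = (n_dk + alpha) / (n_d + alpha.sum())[:, None]
    return TopicModelFit(
        phi=phi,
        p_ia=p_ia,
        loglik_trace=loglik,
        params=params,
        terms=list(dtm.vocabulary.terms),
        row_ids=list(dtm.row_ids),
        alpha=alpha,
        beta=beta,
    )


def top_words(fit: TopicModelFit, topic: int, n: int = 20) -> list[str]:
    """The ``n`` most probable terms of a topic, ties broken lexicographically."""
    if not 0 <= topic < fit.phi.shape[0]:
        raise IndexError(f"topic {topic} out of range")
    row = fit.phi[topic]
    order = sorted(range(len(row)), key=lambda j: (-row[j], fit.terms[j]))
    return [fit.terms[j] for j in order[: min(n, len(row))]]
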