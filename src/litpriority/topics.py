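"""NMF hotspot discovery and topic-number selection.

The term matrix R (n documents x m lemmas) is factorized as R ~ W H with
non-negative W (n x k, document-topic) and H (k x m, topic-term),
minimizing f(W, H) = 1/2 * ||R - WH||_F^2 by alternating nonnegative
least squares (block-coordinate HALS updates, which solve each factor
column exactly and therefore never increase the objective).  The
discovered topics are the corpus's research hotspots; each document is
assigned to the topic with the largest loading in its W row.

The number of topics k is chosen by combining two diagnostics over a
candidate grid:

* **stability** — mean matched top-term agreement (depth-averaged Jaccard,
  Greene-style term stability) between a reference model fit on all
  documents and replicate models fit on random document subsamples; high
  values mean the topic structure is reproducible;
* **divergence** — symmetric Kullback-Leibler divergence (Arun-style)
  between the normalized singular-value distribution of H and the
  normalized column-l2-norm distribution of W; low values indicate a
  well-chosen k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .preprocess import TermMatrix

__all__ = [
    "NMFTopicModel",
    "TopicModel",
    "Hotspot",
    "SelectionDiagnostics",
    "Assignments",
    "fit_nmf",
    "top_terms",
    "assign_documents",
    "doc_topic_probability",
    "average_jaccard",
    "topic_stability",
    "arun_divergence",
    "select_k",
]

_EPS = 1e-12


def _as_dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def _nndsvd(R: np.ndarray, k: int, variant: str, rng: np.random.Generator):
    """Non-negative double SVD initialization (Boutsidis & Gallopoulos).

    ``variant`` is "nndsvd" (zeros kept) or "nndsvdar" (zeros replaced by
    small seeded random values, which breaks ties deterministically).
    """
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    W = np.zeros((R.shape[0], k))
    H = np.zeros((k, R.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            wj, hj = up / max(n_up, _EPS), vp / max(n_vp, _EPS)
        else:
            sigma = n_un * n_vn
            wj, hj = un / max(n_un, _EPS), vn / max(n_vn, _EPS)
        W[:, j] = np.sqrt(S[j] * sigma) * wj
        H[j] = np.sqrt(S[j] * sigma) * hj
    if variant == "nndsvdar":
        avg = R.mean()
        W[W == 0] = rng.uniform(0, avg / 100, size=int((W == 0).sum()))
        H[H == 0] = rng.uniform(0, avg / 100, size=int((H == 0).sum()))
    return W, H


def _hals_update(F: np.ndarray, G: np.ndarray, A: np.ndarray) -> None:
    """One pass of HALS column updates for F given gram A and cross G.

    Solves min ||R - F B||^2 column-block-wise for F >= 0 where
    G = R B^T and A = B B^T; updates F in place.
    """
    k = F.shape[1]
    for j in range(k):
        denom = A[j, j]
        if denom < _EPS:
            F[:, j] = 0.0
            continue
        upd = F[:, j] + (G[:, j] - F @ A[:, j]) / denom
        np.maximum(upd, 0.0, out=F[:, j])


class NMFTopicModel(TransformerMixin, BaseEstimator):
    """Non-negative matrix factorization topic model (Frobenius loss).

    Alternating nonnegative least squares with HALS block updates and
    NNDSVD-based initialization.  Deterministic for a fixed
    ``random_state``; the objective value after every full W/H sweep is
    recorded in ``objective_trace_``.

    Parameters
    ----------
    n_topics : int
        Number of topics k (2 <= k <= min(n_docs, n_terms); k = 1 is
        permitted for degenerate rank-1 checks).
    init : {"nndsvdar", "nndsvd", "random"}
        Factor initialization.
    max_iter : int
        Maximum number of full alternating sweeps.
    tol : float
        Relative objective-decrease stopping threshold per sweep.
    random_state : int
        Seed for initialization randomness.

    Attributes
    ----------
    W_ : ndarray of shape (n_docs, n_topics)
        Document-topic loadings.
    components_ : ndarray of shape (n_topics, n_terms)
        Topic-term weights H.
    objective_ : float
        Final value of 1/2 ||R - WH||_F^2.
    objective_trace_ : ndarray
        Objective after each sweep (non-increasing).
    n_iter_ : int
        Sweeps run.
    converged_ : bool
        Whether the tolerance was met before ``max_iter``.
    """

    def __init__(
        self,
        n_topics: int = 10,
        init: str = "nndsvdar",
        max_iter: int = 300,
        tol: float = 1e-5,
        random_state: int = 0,
    ):
        self.n_topics = n_topics
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        R = _as_dense(X)
        if R.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if (R < 0).any():
            raise ValueError("X must be non-negative")
        n, m = R.shape
        k = int(self.n_topics)
        if k < 1:
            raise ValueError("n_topics must be >= 1")
        if k > min(n, m):
            raise ValueError(f"n_topics={k} exceeds min(n_docs, n_terms)={min(n, m)}")
        rng = np.random.default_rng(self.random_state)
        if self.init == "random":
            scale = np.sqrt(R.mean() / max(k, 1))
            W = rng.uniform(0, 1, (n, k)) * scale
            H = rng.uniform(0, 1, (k, m)) * scale
        elif self.init in ("nndsvd", "nndsvdar"):
            W, H = _nndsvd(R, k, self.init, rng)
        else:
            raise ValueError(f"unknown init: {self.init!r}")

        R2 = float((R * R).sum())
        trace: list[float] = []
        prev = np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            # update W: G = R H^T, A = H H^T
            _hals_update(W, R @ H.T, H @ H.T)
            # update H (transposed role): G = R^T W, A = W^T W
            Ht = H.T
            G = R.T @ W
            A = W.T @ W
            _hals_update(Ht, G, A)
            H = Ht.T
            # objective from the products already at hand:
            # f = 1/2 (||R||^2 - 2 tr(H G) + tr(A H H^T))
            cross = float(np.einsum("km,mk->", H, G))
            quad = float(np.einsum("ij,ji->", A, H @ H.T))
            f = 0.5 * (R2 - 2.0 * cross + quad)
            f = max(f, 0.0)
            trace.append(f)
            if prev - f <= self.tol * max(trace[0], _EPS):
                converged = True
                break
            prev = f
        if not converged:
            warnings.warn(
                f"NMF did not reach tol={self.tol} within {self.max_iter} sweeps",
                RuntimeWarning,
            )
        self.W_ = W
        self.components_ = H
        self.objective_trace_ = np.asarray(trace)
        self.objective_ = trace[-1]
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = m
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).W_

    def transform(self, X):
        """Project new documents onto the fitted topic basis (W given H)."""
        check_is_fitted(self, "components_")
        R = _as_dense(X)
        H = self.components_
        if R.shape[1] != H.shape[1]:
            raise ValueError("X has wrong number of terms")
        rng = np.random.default_rng(self.random_state)
        W = rng.uniform(0, 1, (R.shape[0], H.shape[0])) * np.sqrt(
            max(R.mean(), _EPS) / H.shape[0]
        )
        A = H @ H.T
        G = R @ H.T
        for _ in range(200):
            before = W.copy()
            _hals_update(W, G, A)
            if np.abs(W - before).max() <= 1e-8 * (1 + np.abs(before).max()):
                break
        return W


@dataclass
class TopicModel:
    """Fitted factorization bundle: R ~ W H plus fit diagnostics."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective: float
    seed: int
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    row_ids: tuple[str, ...]
    lemmas: tuple[str, ...]


@dataclass(frozen=True)
class Hotspot:
    """A discovered research hotspot: topic id plus ranked keywords."""

    topic_id: int
    top_terms: tuple[tuple[str, float], ...]
    label: str | None = None


@dataclass
class SelectionDiagnostics:
    """Per-k stability/divergence grid and the selected topic count."""

    k_grid: tuple[int, ...]
    stability: np.ndarray
    divergence: np.ndarray
    k_selected: int
    failed_k: tuple[int, ...] = ()


@dataclass
class Assignments:
    """Hard document-to-topic partition derived from W row argmaxes."""

    by_topic: dict[int, set[str]]
    unassigned: set[str]

    def topic_of(self) -> dict[str, int]:
        return {d: t for t, docs in self.by_topic.items() for d in docs}


def fit_nmf(
    R: TermMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    init: str = "nndsvdar",
) -> TopicModel:
    """Fit the topic model on a term matrix and bundle the result."""
    est = NMFTopicModel(
        n_topics=k, init=init, max_iter=max_iter, tol=tol, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est.fit(R.values)
    return TopicModel(
        W=est.W_,
        H=est.components_,
        k=k,
        objective=est.objective_,
        seed=seed,
        n_iter=est.n_iter_,
        converged=est.converged_,
        objective_trace=est.objective_trace_,
        row_ids=tuple(R.row_ids),
        lemmas=tuple(R.vocabulary.lemmas),
    )


def top_terms(model: TopicModel, topic_id: int, depth: int = 5) -> list[tuple[str, float]]:
    """The ``depth`` heaviest terms of a topic, ties broken lexicographically."""
    if not 0 <= topic_id < model.k:
        raise IndexError(f"topic_id {topic_id} out of range for k={model.k}")
    row = model.H[topic_id]
    depth = min(depth, len(row))
    order = sorted(range(len(row)), key=lambda j: (-row[j], model.lemmas[j]))
    return [(model.lemmas[j], float(row[j])) for j in order[:depth]]


def hotspots(model: TopicModel, depth: int = 5) -> list[Hotspot]:
    """All topics as :class:`Hotspot` records with top-``depth`` keywords."""
    return [
        Hotspot(topic_id=t, top_terms=tuple(top_terms(model, t, depth)))
        for t in range(model.k)
    ]


def assign_documents(model: TopicModel) -> Assignments:
    """Partition documents by W-row argmax (ties to the lowest topic id).

    Documents with an all-zero W row go to an ``unassigned`` bucket and are
    excluded from every topic's document set.
    """
    by_topic: dict[int, set[str]] = {t: set() for t in range(model.k)}
    unassigned: set[str] = set()
    for i, doc_id in enumerate(model.row_ids):
        row = model.W[i]
        if not row.any():
            unassigned.add(doc_id)
            continue
        by_topic[int(np.argmax(row))].add(doc_id)
    return Assignments(by_topic=by_topic, unassigned=unassigned)


def doc_topic_probability(model: TopicModel):
    """Per-topic document membership probabilities p(d|t).

    Column-normalizes W over all documents, so each topic's probabilities
    sum to 1 across the whole corpus.  Raises on a degenerate (all-zero)
    topic column.
    """
    import pandas as pd

    colsum = model.W.sum(axis=0)
    if (colsum <= 0).any():
        bad = np.flatnonzero(colsum <= 0).tolist()
        raise ValueError(f"degenerate all-zero topic column(s): {bad}")
    P = model.W / colsum
    return pd.DataFrame(P, index=list(model.row_ids), columns=range(model.k))


def average_jaccard(list_a, list_b, depth: int | None = None) -> float:
    """Depth-averaged Jaccard agreement of two ranked term lists.

    mean over d = 1..depth of |top_d(a) & top_d(b)| / |top_d(a) | top_d(b)|.
    """
    if depth is None:
        depth = min(len(list_a), len(list_b))
    depth = min(depth, len(list_a), len(list_b))
    if depth == 0:
        return 0.0
    total = 0.0
    for d in range(1, depth + 1):
        a, b = set(list_a[:d]), set(list_b[:d])
        total += len(a & b) / len(a | b)
    return total / depth


def _top_index_lists(H: np.ndarray, depth: int) -> list[np.ndarray]:
    # ranked vocabulary indices per topic; index order breaks ties deterministically
    return [np.argsort(-H[t], kind="stable")[:depth] for t in range(H.shape[0])]


def _match_agreement(ref_lists, run_lists, depth: int) -> float:
    """Mean agreement after Hungarian matching of run topics to reference topics."""
    k = len(ref_lists)
    score = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            score[a, b] = average_jaccard(ref_lists[a], run_lists[b], depth)
    rows, cols = linear_sum_assignment(-score)
    return float(score[rows, cols].mean())


def topic_stability(
    R: TermMatrix,
    k: int,
    n_runs: int = 10,
    sample_frac: float = 0.8,
    depth: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    reference: TopicModel | None = None,
    replicate_init: str = "random",
) -> float:
    """Greene-style term stability of the k-topic structure, in [0, 1].

    Fits a reference model on all documents and ``n_runs`` replicate models
    on random ``sample_frac`` document subsamples; each replicate's topics
    are matched to the reference topics by Hungarian assignment maximizing
    depth-averaged top-term Jaccard agreement, and the mean matched
    agreement is returned (1.0 = perfectly reproducible topics).

    Replicates use random initialization by default: a deterministic
    NNDSVD start makes replicate fits collapse onto near-identical local
    optima even when k is misspecified, inflating the stability of
    over-split solutions; random restarts restore the metric's intended
    sensitivity to genuinely unstable topic structures.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must be in (0, 1]")
    n = R.values.shape[0]
    n_sub = int(round(sample_frac * n))
    if k > min(n_sub, R.values.shape[1]):
        raise ValueError("k exceeds the rank available in subsamples")
    if reference is None:
        reference = fit_nmf(R, k, seed=seed, max_iter=max_iter, tol=tol)
    ref_lists = _top_index_lists(reference.H, depth)
    rng = np.random.default_rng(seed)
    dense = _as_dense(R.values)
    scores = []
    for r in range(n_runs):
        idx = rng.choice(n, size=n_sub, replace=False)
        est = NMFTopicModel(
            n_topics=k,
            init=replicate_init,
            max_iter=max_iter,
            tol=tol,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est.fit(dense[idx])
        run_lists = _top_index_lists(est.components_, depth)
        scores.append(_match_agreement(ref_lists, run_lists, depth))
    return float(np.mean(scores))


def arun_divergence(model: TopicModel, eps: float = _EPS) -> float:
    """Symmetric KL divergence between H's singular-value distribution and
    W's column-norm distribution (low = well-chosen k)."""
    if model.k == 1:
        warnings.warn("divergence undefined for k=1; returning 0", RuntimeWarning)
        return 0.0
    u = np.linalg.svd(model.H, compute_uv=False)
    v = np.linalg.norm(model.W, axis=0)  # per-topic l2 norm of loadings
    u = np.maximum(u, eps)
    v = np.maximum(v, eps)
    u = u / u.sum()
    v = v / v.sum()
    return float(np.sum(u * np.log(u / v)) + np.sum(v * np.log(v / u)))


def select_k(
    R: TermMatrix,
    k_min: int = 5,
    k_max: int = 30,
    step: int = 1,
    n_runs: int = 10,
    sample_frac: float = 0.8,
    depth: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    stability_tol: float = 0.05,
    divergence_tol: float = 0.10,
) -> SelectionDiagnostics:
    """Scan a k grid and pick the k with high stability and low divergence.

    Combination rule: shortlist the candidates whose stability is within
    ``stability_tol`` of the grid maximum, drop shortlisted candidates
    whose divergence exceeds the shortlist minimum by more than
    ``divergence_tol``, and select the *largest* remaining k.  Preferring
    the richer structure among jointly near-optimal candidates mirrors how
    the two diagnostics are combined in practice: gross under-fitting
    merges distinct topics into vague composites that can look both stable
    and low-divergence, so when a small and a large k are otherwise tied
    the larger, more articulated structure is the better model.  The full
    grid is returned so a practitioner can override the automatic choice
    after inspecting the diagnostics.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    grid = list(range(k_min, k_max + 1, step))
    stab, div, kept, failed = [], [], [], []
    for k in grid:
        try:
            ref = fit_nmf(R, k, seed=seed, max_iter=max_iter, tol=tol)
            s = topic_stability(
                R,
                k,
                n_runs=n_runs,
                sample_frac=sample_frac,
                depth=depth,
                seed=seed + k,
                max_iter=max_iter,
                tol=tol,
                reference=ref,
            )
            d = arun_divergence(ref)
        except ValueError as exc:  # pragma: no cover - propagated per-k failure
            warnings.warn(f"k={k} skipped: {exc}", RuntimeWarning)
            failed.append(k)
            continue
        kept.append(k)
        stab.append(s)
        div.append(d)
    if not kept:
        raise ValueError("no candidate k could be fitted")
    stab_arr = np.asarray(stab)
    div_arr = np.asarray(div)
    shortlist = np.flatnonzero(stab_arr >= stab_arr.max() - stability_tol)
    d_min = div_arr[shortlist].min()
    shortlist = shortlist[div_arr[shortlist] <= d_min + divergence_tol]
    best = int(shortlist.max())  # richest structure among joint near-optima
    return SelectionDiagnostics(
        k_grid=tuple(kept),
        stability=stab_arr,
        divergence=div_arr,
        k_selected=kept[best],
        failed_k=tuple(failed),
    )
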