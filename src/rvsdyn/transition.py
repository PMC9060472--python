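"""Exact one-generation transition kernel on enumerated composition spaces.

The chain over compositions ``n`` (counts per type, summing to N) moves in
one generation from source ``n'`` to destination ``n`` with a multinomial
probability: N independent slots, each filled with type γ with probability
``selection_probabilities(spec, n')[γ]``.  All matrices in this module use
the destination-row / source-column convention ``W[dest, source]``, so
every column of a transition matrix sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import comb, gammaln, xlogy

from .errors import NonConvergenceError, ReducibleChainError, SizeCapError
from .model import ModelSpec, check_composition, selection_probabilities

#: default refusal threshold for full state-space enumeration
STATE_CAP = 200_000


@dataclass(frozen=True)
class CompositionSpace:
    """All compositions of N organisms over K types, in a fixed order.

    Ordering is lexicographic *descending* in ``n[0]``, then ``n[1]``, …,
    so for K=2, N=3 the order is (3,0), (2,1), (1,2), (0,3).  The order is
    deterministic and is the index order of every vector/matrix built on
    the space.
    """

    K: int
    N: int
    compositions: np.ndarray  # (S, K) int64

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {tuple(row): i for i, row in enumerate(self.compositions)}
        )

    def __len__(self) -> int:
        return self.compositions.shape[0]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.compositions)

    def index(self, n) -> int:
        """Integer index of a composition; KeyError if not in the space."""
        return self._index[tuple(int(x) for x in np.atleast_1d(n))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.compositions, columns=[f"n{i}" for i in range(self.K)]
        )
        df.insert(0, "state", np.arange(len(self)))
        return df


def _compositions_desc(K: int, N: int):
    if K == 1:
        yield (N,)
        return
    for n1 in range(N, -1, -1):
        for rest in _compositions_desc(K - 1, N - n1):
            yield (n1, *rest)


def space_size(K: int, N: int) -> int:
    """Number of compositions, binomial(N + K - 1, K - 1) (stars and bars)."""
    return int(comb(N + K - 1, K - 1, exact=True))


def enumerate_compositions(K: int, N: int, cap: int = STATE_CAP) -> CompositionSpace:
    """Enumerate the full composition space for K types and N organisms.

    Refuses spaces larger than ``cap`` states; use the simulation module
    for sampling-based estimates on such models.
    """
    if K < 1 or N < 1:
        raise ValueError("K and N must be >= 1")
    size = space_size(K, N)
    if size > cap:
        raise SizeCapError(
            f"composition space for K={K}, N={N} has {size} states, "
            f"exceeding the cap of {cap}; raise `cap` explicitly or use "
            "Monte-Carlo simulation instead"
        )
    comps = np.array(list(_compositions_desc(K, N)), dtype=np.int64)
    return CompositionSpace(K=K, N=N, compositions=comps)


def log_transition_probability(spec: ModelSpec, dest, source) -> float:
    """Log of the one-generation probability of ``dest <- source``.

    Multinomial log-pmf evaluated in log space via log-gamma; returns
    ``-inf`` exactly when some destination type has zero selection
    probability but a positive count.
    """
    d = check_composition(spec, dest)
    p = selection_probabilities(spec, source)
    return float(
        gammaln(spec.N + 1) - gammaln(d + 1).sum() + xlogy(d, p).sum()
    )


def transition_probability(spec: ModelSpec, dest, source) -> float:
    """One-generation probability ``W[dest <- source]`` (see log variant)."""
    return float(np.exp(log_transition_probability(spec, dest, source)))


def selection_probability_matrix(spec: ModelSpec, space: CompositionSpace) -> np.ndarray:
    """(S, K) matrix whose row j is ``selection_probabilities`` from state j."""
    C = space.compositions
    weights = spec.f[None, :] * (C @ spec.pi.T)
    totals = weights.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = int(np.argmin(totals))
        # trigger the standard degenerate-model error message
        selection_probabilities(spec, C[bad])
    return weights / totals


def log_transition_matrix(spec: ModelSpec, space: CompositionSpace) -> np.ndarray:
    """(S, S) matrix of log transition probabilities, ``[dest, source]``."""
    _check_space(spec, space)
    C = space.compositions
    P = selection_probability_matrix(spec, space)
    base = gammaln(spec.N + 1) - gammaln(C + 1).sum(axis=1)  # per destination
    S = len(space)
    logW = np.empty((S, S))
    with np.errstate(divide="ignore"):
        for j in range(S):
            logW[:, j] = base + xlogy(C, P[j][None, :]).sum(axis=1)
    return logW


def _check_space(spec: ModelSpec, space: CompositionSpace) -> None:
    if space.K != spec.K or space.N != spec.N:
        raise ValueError(
            f"space is for K={space.K}, N={space.N}; model has K={spec.K}, N={spec.N}"
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic transition matrix ``W[dest, source]`` on a space."""

    W: np.ndarray
    space: CompositionSpace

    def __post_init__(self):
        colsum = self.W.sum(axis=0)
        if np.any(self.W < 0) or np.max(np.abs(colsum - 1.0)) > 1e-10:
            raise ValueError("transition matrix is not column-stochastic")

    @property
    def is_positive(self) -> bool:
        """True when every entry is strictly positive (ergodicity certificate)."""
        return bool(np.all(self.W > 0))

    def to_triplets(self) -> pd.DataFrame:
        dest, source = np.nonzero(self.W)
        return pd.DataFrame(
            {
                "dest_index": dest,
                "source_index": source,
                "probability": self.W[dest, source],
            }
        )


def transition_matrix(spec: ModelSpec, space: CompositionSpace) -> TransitionMatrix:
    """Exact transition matrix of the one-generation dynamics on ``space``."""
    return TransitionMatrix(W=np.exp(log_transition_matrix(spec, space)), space=space)


# ---------------------------------------------------------------------------
# Stationary distributions
# ---------------------------------------------------------------------------


def recurrent_classes(W: np.ndarray) -> list[list[int]]:
    """Recurrent classes of the chain: strongly connected components of the
    positive-support graph with no outgoing edges to other components."""
    support = csr_matrix((W > 0).T.astype(np.int8))  # edge j -> i iff W[i, j] > 0
    ncomp, labels = connected_components(support, directed=True, connection="strong")
    has_exit = np.zeros(ncomp, dtype=bool)
    rows, cols = (W > 0).nonzero()
    for i, j in zip(rows, cols):  # transition j -> i
        if labels[i] != labels[j]:
            has_exit[labels[j]] = True
    return [
        sorted(np.flatnonzero(labels == c).tolist())
        for c in range(ncomp)
        if not has_exit[c]
    ]


def stationary_distribution(
    W: TransitionMatrix | np.ndarray,
    method: str = "power",
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    check_reducible: bool = True,
) -> np.ndarray:
    """Stationary probability vector of a column-stochastic matrix.

    ``method="power"`` (default) iterates ``p <- W p`` until the L1 residual
    drops below ``tol``; ``method="dense"`` solves the eigenproblem
    directly (small spaces).  When the chain has more than one recurrent
    class the stationary vector is not unique and a
    :class:`~rvsdyn.errors.ReducibleChainError` carrying all recurrent
    classes is raised instead of silently returning one of them.
    """
    M = W.W if isinstance(W, TransitionMatrix) else np.asarray(W, dtype=float)
    if check_reducible:
        classes = recurrent_classes(M)
        if len(classes) > 1:
            raise ReducibleChainError(
                f"chain is reducible with {len(classes)} recurrent classes; "
                "the stationary distribution is not unique",
                recurrent_classes=classes,
            )
    if method == "dense":
        vals, vecs = np.linalg.eig(M)
        k = int(np.argmin(np.abs(vals - 1.0)))
        p = np.real(vecs[:, k])
        p = np.abs(p)
        p /= p.sum()
        return p
    if method != "power":
        raise ValueError(f"unknown method {method!r}")
    p = np.full(M.shape[0], 1.0 / M.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        q = M @ p
        residual = float(np.abs(q - p).sum())
        p = q
        if residual <= tol:
            p = np.clip(p, 0.0, None)
            return p / p.sum()
    raise NonConvergenceError(
        f"power iteration did not reach tol={tol:g} within {max_iter} steps "
        f"(last residual {residual:.3g})",
        residual=residual,
    )


def evolve(W: TransitionMatrix | np.ndarray, p0: np.ndarray, T: int) -> np.ndarray:
    """Propagate a composition distribution forward by ``T`` generations."""
    M = W.W if isinstance(W, TransitionMatrix) else np.asarray(W, dtype=float)
    p = np.asarray(p0, dtype=float)
    for _ in range(T):
        p = M @ p
    return p


def stationary_to_frame(space: CompositionSpace, p: np.ndarray) -> pd.DataFrame:
    df = space.to_frame()
    df["probability"] = p
    return df
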