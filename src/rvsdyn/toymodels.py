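"""Builders for the illustrative models and random fixtures.

Three families:

* a two-type model (symmetric variation probability μ ≤ 1/2, the faster
  type first) whose N=3 composition space has four states and exhibits
  every force class in miniature;
* a square-grid landscape where each lattice site is a type, variations
  hop between 4-neighbors, and islands of fast-reproducing types of
  different connectivity sit in a sea of slow ones — the setting in which
  robustness emerges from the expected-growth force alone;
* seeded random models (log-uniform rates, reversible sparse kernels) for
  property-based testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelValidationError
from .model import ModelSpec, TypeSpace, VariationKernel


def two_type_model(
    f1: float, f2: float, mu: float, N: int, labels: tuple[str, str] = ("g1", "g2")
) -> ModelSpec:
    """Two types varying into each other with the same probability μ.

    The kernel is symmetric with diagonal 1-μ, so μ_γ = μ for both types.
    μ must lie in (0, 1/2]; by convention the first type is the faster
    one (a warning, not an error, if violated).
    """
    if not 0 < mu <= 0.5:
        raise ModelValidationError(
            f"mu must lie in (0, 0.5], got {mu}: beyond 1/2 a variation would "
            "be more likely than no variation"
        )
    if not f1 > f2 > 0:
        warnings.warn(
            "two_type_model conventionally takes f1 > f2 > 0", stacklevel=2
        )
    pi = np.array([[1 - mu, mu], [mu, 1 - mu]])
    return ModelSpec(TypeSpace(labels, np.array([f1, f2])), VariationKernel(pi), N)


@dataclass(frozen=True)
class GridLayout:
    """A rectangular lattice of types: fast sites in a slow sea.

    ``fast_mask[r, c]`` marks fast sites; ``mu_bar`` is the constant
    per-type variation probability; ``groups`` optionally names site sets
    (e.g. "island_interior", "strip", "isolated") for occupancy summaries.
    """

    width: int
    height: int
    fast_mask: np.ndarray
    f_fast: float = 2.0
    f_slow: float = 1.0
    mu_bar: float = 0.1
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        mask = np.asarray(self.fast_mask, dtype=bool)
        if mask.shape != (self.height, self.width):
            raise ModelValidationError(
                f"fast_mask shape {mask.shape} does not match "
                f"(height, width) = ({self.height}, {self.width})"
            )
        object.__setattr__(self, "fast_mask", mask)
        if not self.f_fast > self.f_slow > 0:
            raise ModelValidationError("need f_fast > f_slow > 0")
        if not 0 < self.mu_bar < 1:
            raise ModelValidationError("need 0 < mu_bar < 1")

    def site_label(self, r: int, c: int) -> str:
        return f"r{r}c{c}"


def grid_model(
    layout: GridLayout, N: int = 100, neighbor_weight: str = "degree"
) -> ModelSpec:
    """One type per lattice site; variations hop to 4-neighbors.

    With ``neighbor_weight="degree"`` (default) each neighbor of a site
    receives probability ``mu_bar / deg`` where deg is the actual
    neighbor count (2 at corners, 3 on edges, 4 inside; no wrap-around),
    so every site has exactly μ_γ = mu_bar — the constant variation
    coefficient.  ``neighbor_weight="quarter"`` instead assigns
    ``mu_bar / 4`` per neighbor, which makes boundary sites vary less.
    The kernel is reversible by construction.
    """
    if neighbor_weight not in ("degree", "quarter"):
        raise ValueError(f"unknown neighbor_weight {neighbor_weight!r}")
    H, W = layout.height, layout.width
    K = H * W
    idx = lambda r, c: r * W + c  # noqa: E731
    labels, f, coords = [], np.empty(K), np.empty((K, 2))
    for r in range(H):
        for c in range(W):
            k = idx(r, c)
            labels.append(layout.site_label(r, c))
            f[k] = layout.f_fast if layout.fast_mask[r, c] else layout.f_slow
            coords[k] = (c, r)
    pi = np.zeros((K, K))
    for r in range(H):
        for c in range(W):
            k = idx(r, c)
            nbrs = [
                idx(rr, cc)
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if 0 <= rr < H and 0 <= cc < W
            ]
            share = layout.mu_bar / (len(nbrs) if neighbor_weight == "degree" else 4)
            for j in nbrs:
                pi[j, k] = share
            pi[k, k] = 1.0 - share * len(nbrs)
    return ModelSpec(TypeSpace(tuple(labels), f, coords), VariationKernel(pi), N=N)


def box2_layout(
    width: int = 12,
    height: int = 12,
    f_fast: float = 2.0,
    f_slow: float = 1.0,
    mu_bar: float = 0.4,
) -> GridLayout:
    """Default landscape: one compact fast island, one fast strip, and
    isolated fast sites, differing only by connectivity.

    * a 4x4 island (rows 1-4, cols 1-4) whose 2x2 interior sites have all
      four neighbors fast;
    * a 1x6 strip (row 8, cols 1-6) whose sites have at most two fast
      neighbors;
    * four isolated fast sites with no fast neighbor at all.

    The named ``groups`` expose exactly these site sets so occupancy
    summaries can compare them.
    """
    mask = np.zeros((height, width), dtype=bool)
    island = [(r, c) for r in range(1, 5) for c in range(1, 5)]
    interior = [(r, c) for r in range(2, 4) for c in range(2, 4)]
    strip = [(8, c) for c in range(1, 7)]
    isolated = [(2, 8), (5, 10), (10, 2), (10, 9)]
    for r, c in island + strip + isolated:
        mask[r, c] = True
    return GridLayout(
        width=width,
        height=height,
        fast_mask=mask,
        f_fast=f_fast,
        f_slow=f_slow,
        mu_bar=mu_bar,
        groups={
            "island": island,
            "island_interior": interior,
            "strip": strip,
            "isolated": isolated,
        },
    )


def random_model(
    K: int,
    N: int,
    seed=None,
    f_range: tuple[float, float] = (0.5, 2.0),
    mu_range: tuple[float, float] = (0.05, 0.3),
    density: float = 0.5,
    uniform_kernel: bool = False,
) -> ModelSpec:
    """Seeded random model for property tests.

    Rates are log-uniform in ``f_range``.  The kernel support is a
    symmetrized random sparse pattern augmented with a ring so every type
    can vary (reversibility and μ_γ > 0 guaranteed); each column's
    off-diagonal mass μ_γ is uniform in ``mu_range`` and spread over the
    supported entries with random positive weights.  With
    ``uniform_kernel=True`` the kernel is the flat matrix 1/K (the
    source-independent, zero-ζ fixture).  ``seed`` may be an int, a
    SeedSequence, or an existing Generator (reused, not reset).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = np.log(f_range[0]), np.log(f_range[1])
    f = np.exp(rng.uniform(lo, hi, size=K))
    labels = tuple(f"t{i}" for i in range(K))
    if K == 1:
        return ModelSpec(TypeSpace(labels, f), VariationKernel(np.ones((1, 1))), N)
    if uniform_kernel:
        pi = np.full((K, K), 1.0 / K)
        return ModelSpec(TypeSpace(labels, f), VariationKernel(pi), N)
    support = rng.random((K, K)) < density
    support = support | support.T  # reversible support
    ring = np.roll(np.eye(K, dtype=bool), 1, axis=0)
    support |= ring | ring.T  # every type has at least one variation channel
    np.fill_diagonal(support, False)
    weights = np.where(support, rng.random((K, K)) + 0.1, 0.0)
    mu = rng.uniform(*mu_range, size=K)
    pi = weights / weights.sum(axis=0, keepdims=True) * mu[None, :]
    pi[np.diag_indices(K)] = 1.0 - mu
    return ModelSpec(TypeSpace(labels, f), VariationKernel(pi), N)
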