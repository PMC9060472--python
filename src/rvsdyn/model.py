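"""Parameterization of reproduction–variation–selection (RVS) population dynamics.

The model describes a population of ``N`` organisms, each belonging to a
discrete type γ.  One generation consists of three stages:

1. *Variation*: an organism of type γ′ turns into type γ with probability
   ``pi[γ, γ′]`` (a column-stochastic matrix; the diagonal is the
   probability of no change, so ``mu[γ] = 1 - pi[γ, γ]`` is the overall
   per-generation variation probability of type γ).
2. *Reproduction*: a type-γ organism produces offspring at rate ``f[γ]``
   (a dimensionless positive weight; only ratios matter for selection).
3. *Selection*: the next generation of exactly ``N`` organisms is drawn
   multinomially, each slot filled with type γ with probability
   proportional to ``f[γ] * (pi @ n)[γ]``.

The chain state is the composition vector ``n`` (non-negative integer
counts per type, summing to ``N``).  Rescaling all rates by a common
positive constant leaves the selection probabilities — and hence the whole
dynamics — unchanged; potentials defined elsewhere in the package shift by
an additive constant under such a rescaling while the directionality (log
ratio of forward/backward transition probabilities) is invariant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateModelError, ModelValidationError

#: tolerance on |column sum - 1| for variation kernels
COLUMN_SUM_TOL = 1e-10


def _kernel_violations(pi: np.ndarray, tol: float = COLUMN_SUM_TOL) -> list[str]:
    """Structural violations of a candidate variation kernel, as messages."""
    out: list[str] = []
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 2 or pi.shape[0] != pi.shape[1]:
        return [f"kernel must be square, got shape {pi.shape}"]
    if not np.all(np.isfinite(pi)):
        out.append("kernel contains non-finite entries")
        return out
    neg = np.argwhere(pi < 0)
    for i, j in neg[:5]:
        out.append(f"negative entry pi[{i}, {j}] = {pi[i, j]:g}")
    colsum = pi.sum(axis=0)
    bad = np.flatnonzero(np.abs(colsum - 1.0) > tol)
    for j in bad:
        out.append(f"column {j} sums to {colsum[j]:.12g} (expected 1)")
    # reversibility of the support: pi[i, j] > 0 <=> pi[j, i] > 0
    support = pi > 0
    asym = np.argwhere(support & ~support.T)
    for i, j in asym:
        if i < j or not support[j, i]:
            out.append(
                f"irreversible variation: pi[{i}, {j}] > 0 but pi[{j}, {i}] = 0"
            )
    return out


@dataclass(frozen=True)
class TypeSpace:
    """The set of organism types with their reproduction rates.

    Ordering is the insertion order of ``labels`` and is the index order of
    every vector and matrix in the package.  ``coords`` optionally carries
    2-D layout coordinates (used by grid models); it plays no dynamical role.
    """

    labels: tuple[str, ...]
    f: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        f = np.atleast_1d(np.asarray(self.f, dtype=float))
        if len(labels) != f.size:
            raise ModelValidationError(
                f"{len(labels)} labels but {f.size} reproduction rates"
            )
        if len(set(labels)) != len(labels):
            raise ModelValidationError("type labels must be unique")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ModelValidationError(
                "reproduction rates must be strictly positive and finite"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "f", f)
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (f.size, 2):
                raise ModelValidationError("coords must have shape (K, 2)")
            object.__setattr__(self, "coords", coords)

    @property
    def K(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class VariationKernel:
    """Column-stochastic matrix of per-generation variation probabilities.

    ``pi[dest, source]`` is the probability that one organism of the source
    type turns into the destination type during a single generation.  The
    support is required to be reversible: a variation that can happen must
    also be possible in the opposite direction (possibly with a very
    different probability).
    """

    pi: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        pi = np.atleast_2d(np.asarray(self.pi, dtype=float))
        object.__setattr__(self, "pi", pi)
        if self.validate:
            problems = _kernel_violations(pi)
            if problems:
                raise ModelValidationError("; ".join(problems))

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def mu(self) -> np.ndarray:
        """Overall variation probability per type, ``1 - diag(pi)``."""
        return 1.0 - np.diag(self.pi)

    def renormalized(self) -> "VariationKernel":
        """Return a copy with each column rescaled to sum exactly to 1.

        Renormalization is never applied silently; callers must opt in.
        """
        colsum = self.pi.sum(axis=0)
        if np.any(colsum <= 0):
            raise ModelValidationError("cannot renormalize a zero column")
        return VariationKernel(self.pi / colsum)


def variation_probability(kernel: VariationKernel | np.ndarray) -> np.ndarray:
    """Per-type overall variation probability ``mu[γ] = 1 - pi[γ, γ]``.

    Equivalently the sum of off-diagonal entries of column γ.  Accepts a raw
    matrix, in which case it is validated first.
    """
    if not isinstance(kernel, VariationKernel):
        kernel = VariationKernel(kernel)
    return kernel.mu


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterization of an RVS dynamics: types, kernel and N."""

    types: TypeSpace
    kernel: VariationKernel
    N: int

    def __post_init__(self):
        if self.kernel.K != self.types.K:
            raise ModelValidationError(
                f"kernel is {self.kernel.K}x{self.kernel.K} "
                f"but there are {self.types.K} types"
            )
        if int(self.N) != self.N or self.N < 1:
            raise ModelValidationError(f"N must be a positive integer, got {self.N}")
        object.__setattr__(self, "N", int(self.N))

    # convenience views -------------------------------------------------
    @property
    def K(self) -> int:
        return self.types.K

    @property
    def f(self) -> np.ndarray:
        return self.types.f

    @property
    def pi(self) -> np.ndarray:
        return self.kernel.pi

    @property
    def labels(self) -> tuple[str, ...]:
        return self.types.labels

    @property
    def mu(self) -> np.ndarray:
        return self.kernel.mu

    def rescaled(self, c: float) -> "ModelSpec":
        """Model with all reproduction rates multiplied by ``c > 0``."""
        if c <= 0:
            raise ModelValidationError("rate scale factor must be positive")
        return ModelSpec(
            TypeSpace(self.labels, self.f * c, self.types.coords), self.kernel, self.N
        )


def check_composition(spec: ModelSpec, n: Sequence[int] | np.ndarray) -> np.ndarray:
    """Validate and return a composition vector for ``spec`` as an int array."""
    n = np.atleast_1d(np.asarray(n))
    if n.shape != (spec.K,):
        raise ModelValidationError(
            f"composition has {n.size} entries, model has {spec.K} types"
        )
    ni = np.asarray(np.rint(n), dtype=np.int64)
    if not np.allclose(n, ni):
        raise ModelValidationError("composition entries must be integers")
    if np.any(ni < 0):
        raise ModelValidationError("composition entries must be non-negative")
    if ni.sum() != spec.N:
        raise ModelValidationError(
            f"composition sums to {ni.sum()}, expected N = {spec.N}"
        )
    return ni


def selection_probabilities(spec: ModelSpec, source) -> np.ndarray:
    """Probability that a next-generation slot is filled by each type.

    Given the current composition ``n'``, the probability of selecting type
    γ is ``f[γ] (pi @ n')[γ]`` normalized over types: variations reshape the
    pool, reproduction rates weight it.  Invariant under ``f -> c f``.
    """
    n = check_composition(spec, source)
    weights = spec.f * (spec.pi @ n)
    total = weights.sum()
    if total <= 0:
        raise DegenerateModelError(
            "all selection weights vanish for composition "
            f"{tuple(n)}: no type has f * (pi @ n) > 0"
        )
    return weights / total


@dataclass(frozen=True)
class ValidationReport:
    """Report-only diagnostics for a model; callers decide whether to escalate."""

    violations: tuple[str, ...]
    colsum_residual: float
    all_rates_positive: bool
    all_mu_positive: bool

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_model(spec: ModelSpec) -> ValidationReport:
    """Diagnose a model: rate positivity, column stochasticity, reversibility.

    ``all_mu_positive`` is an ergodicity hint: together with positive rates
    it guarantees a strictly positive transition kernel on the full
    composition space, hence a unique stationary distribution.
    """
    violations: list[str] = []
    f = spec.f
    rates_ok = bool(np.all(np.isfinite(f)) and np.all(f > 0))
    if not rates_ok:
        violations.append("non-positive or non-finite reproduction rate")
    violations.extend(_kernel_violations(spec.pi))
    colsum_residual = float(np.max(np.abs(spec.pi.sum(axis=0) - 1.0)))
    mu = 1.0 - np.diag(spec.pi)
    return ValidationReport(
        violations=tuple(violations),
        colsum_residual=colsum_residual,
        all_rates_positive=rates_ok,
        all_mu_positive=bool(np.all(mu > 0)),
    )


def model_hash(spec: ModelSpec) -> str:
    """Stable content hash of a model (labels, rates, kernel, N)."""
    h = hashlib.sha256()
    h.update("\x1f".join(spec.labels).encode())
    h.update(np.ascontiguousarray(spec.f, dtype=float).tobytes())
    h.update(np.ascontiguousarray(spec.pi, dtype=float).tobytes())
    h.update(str(spec.N).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Tabular I/O: type table (TSV), kernel (dense or triplet TSV), YAML bundle
# ---------------------------------------------------------------------------


def read_type_table(path) -> TypeSpace:
    """Read a TSV with columns ``type_id``, ``f`` and optional ``x``, ``y``."""
    df = pd.read_csv(path, sep="\t", dtype={"type_id": str})
    if "type_id" not in df.columns or "f" not in df.columns:
        raise ModelValidationError(
            f"type table {path} must have columns type_id and f"
        )
    coords = None
    if {"x", "y"}.issubset(df.columns):
        coords = df[["x", "y"]].to_numpy(dtype=float)
    return TypeSpace(tuple(df["type_id"]), df["f"].to_numpy(dtype=float), coords)


def write_type_table(types: TypeSpace, path) -> None:
    df = pd.DataFrame({"type_id": types.labels, "f": types.f})
    if types.coords is not None:
        df["x"] = types.coords[:, 0]
        df["y"] = types.coords[:, 1]
    df.to_csv(path, sep="\t", index=False)


def read_kernel_dense(path, labels: Sequence[str]) -> np.ndarray:
    """Dense kernel TSV: first column = destination type id, remaining
    columns = source type ids; reordered to match ``labels``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    labels = [str(x) for x in labels]
    missing = set(labels) - set(df.index) | set(labels) - set(df.columns)
    if missing:
        raise ModelValidationError(f"kernel table missing types: {sorted(missing)}")
    return df.loc[labels, labels].to_numpy(dtype=float)


def read_kernel_triplets(
    path, labels: Sequence[str], infer_diagonal: bool = False
) -> np.ndarray:
    """Sparse kernel TSV with columns ``source_id``, ``target_id``,
    ``probability``.

    With ``infer_diagonal=True`` the no-variation probability of each
    column is set to 1 minus the listed off-diagonal mass (an explicit
    opt-in; listed diagonal entries are then an error).
    """
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    labels = [str(x) for x in labels]
    idx = {lab: i for i, lab in enumerate(labels)}
    K = len(labels)
    pi = np.zeros((K, K))
    for _, row in df.iterrows():
        try:
            j, i = idx[row["source_id"]], idx[row["target_id"]]
        except KeyError as e:
            raise ModelValidationError(f"unknown type id {e} in kernel triplets")
        if infer_diagonal and i == j:
            raise ModelValidationError(
                "diagonal entries listed while infer_diagonal=True"
            )
        pi[i, j] += float(row["probability"])
    if infer_diagonal:
        off = pi.sum(axis=0) - np.diag(pi)
        if np.any(off > 1 + COLUMN_SUM_TOL):
            j = int(np.argmax(off))
            raise ModelValidationError(
                f"column {labels[j]} has off-diagonal mass {off[j]:g} > 1"
            )
        pi[np.diag_indices(K)] = 1.0 - off
    return pi


def load_model(path) -> ModelSpec:
    """Load a YAML model bundle referencing the two tables plus N.

    Keys: ``types`` (TSV path), ``kernel`` (TSV path), ``kernel_format``
    (``dense`` | ``triplet``), ``N``, optional ``infer_diagonal``.
    Relative paths are resolved against the bundle's directory.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent
    types = read_type_table(base / cfg["types"])
    fmt = cfg.get("kernel_format", "dense")
    if fmt == "dense":
        pi = read_kernel_dense(base / cfg["kernel"], types.labels)
    elif fmt == "triplet":
        pi = read_kernel_triplets(
            base / cfg["kernel"], types.labels,
            infer_diagonal=bool(cfg.get("infer_diagonal", False)),
        )
    else:
        raise ModelValidationError(f"unknown kernel_format {fmt!r}")
    return ModelSpec(types, VariationKernel(pi), int(cfg["N"]))


def save_model(spec: ModelSpec, directory, name: str = "model") -> Path:
    """Write the bundle (YAML + two TSVs) and return the YAML path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_type_table(spec.types, directory / f"{name}_types.tsv")
    dense = pd.DataFrame(spec.pi, index=spec.labels, columns=spec.labels)
    dense.index.name = "type_id"
    dense.to_csv(directory / f"{name}_kernel.tsv", sep="\t")
    bundle = {
        "types": f"{name}_types.tsv",
        "kernel": f"{name}_kernel.tsv",
        "kernel_format": "dense",
        "N": int(spec.N),
    }
    out = directory / f"{name}.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(bundle, fh)
    return out
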