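"""Hyperparameter search space for random-forest tuning.

Candidate solutions ("wolves") move in the normalized unit cube ``[0, 1]^d``;
each coordinate is decoded to a concrete hyperparameter value only when a
classifier has to be trained.  Working in normalized space keeps the swarm
update equations scale-free across mixed integer/continuous dimensions with
very different ranges.

The default space has three dimensions:

* ``n_trees``    — ensemble size, integer in [50, 200]
* ``max_depth``  — tree depth cap, integer in [5, 15]
* ``p_features`` — fraction of features considered per split, continuous in
  (0.3, 0.8] (open at the lower end)

``min_samples_leaf`` is a fixed classifier setting (default 5), not a searched
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "Dimension",
    "HyperparameterSpace",
    "CandidateVector",
    "RFConfig",
    "default_space",
    "sample_uniform",
    "decode",
    "repair",
    "space_from_yaml",
]

#: nudge applied when a bound is open, so decoded values stay strictly inside
_OPEN_EPS = 1e-9


@dataclass(frozen=True)
class Dimension:
    """One searched hyperparameter dimension.

    ``lower_open`` / ``upper_open`` mark half-open interval ends; an open end
    is enforced at decode time by nudging the image by ``1e-9``.
    """

    name: str
    kind: str  # "integer" | "continuous"
    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("integer", "continuous"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ValueError(
                f"dimension {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )


@dataclass(frozen=True)
class HyperparameterSpace:
    """Ordered collection of searched dimensions."""

    dims: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(self.dims))
        if not self.dims:
            raise ValueError("a search space needs at least one dimension")

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dims)


@dataclass
class CandidateVector:
    """A candidate solution in normalized coordinates, with optional fitness."""

    coords: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    def copy(self) -> "CandidateVector":
        return CandidateVector(self.coords.copy(), self.fitness)


@dataclass(frozen=True)
class RFConfig:
    """Concrete random-forest settings produced by decoding a candidate."""

    n_trees: int
    max_depth: int
    p_features: float
    min_samples_leaf: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.p_features <= 1:
            raise ValueError("p_features must lie in (0, 1]")


def default_space() -> HyperparameterSpace:
    """The three-dimensional tuning domain used throughout the package."""
    return HyperparameterSpace(
        dims=(
            Dimension("n_trees", "integer", 50, 200),
            Dimension("max_depth", "integer", 5, 15),
            Dimension("p_features", "continuous", 0.3, 0.8, lower_open=True),
        )
    )


def sample_uniform(
    space: HyperparameterSpace, n: int, rng: np.random.Generator
) -> list[CandidateVector]:
    """Draw ``n`` candidates uniformly from the unit cube.

    Deterministic under a fixed generator state.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    coords = rng.uniform(0.0, 1.0, size=(n, space.n_dims))
    return [CandidateVector(c) for c in coords]


def repair(v: CandidateVector) -> CandidateVector:
    """Clamp every coordinate into [0, 1].

    Idempotent; an in-bounds vector is returned with identical coordinates.
    """
    return CandidateVector(np.clip(v.coords, 0.0, 1.0), v.fitness)


def decode(space: HyperparameterSpace, v: CandidateVector) -> RFConfig:
    """Map a repaired candidate to classifier settings.

    Integer dims use ``round(lower + coord * (upper - lower))``; continuous
    dims use the same affine map, with open interval ends nudged inward.
    Monotone per dimension.
    """
    coords = np.asarray(v.coords, dtype=float)
    if coords.shape != (space.n_dims,):
        raise ValueError(
            f"candidate has {coords.shape} coords, space has {space.n_dims} dims"
        )
    if np.any(coords < 0.0) or np.any(coords > 1.0):
        raise ValueError("candidate must be repaired (all coords in [0, 1]) before decoding")

    values: dict[str, float] = {}
    for dim, c in zip(space.dims, coords):
        x = dim.lower + c * (dim.upper - dim.lower)
        if dim.kind == "integer":
            x = int(round(x))
            if dim.lower_open and x <= dim.lower:
                x = int(dim.lower) + 1
            if dim.upper_open and x >= dim.upper:
                x = int(dim.upper) - 1
        else:
            if dim.lower_open and x <= dim.lower:
                x = dim.lower + _OPEN_EPS
            if dim.upper_open and x >= dim.upper:
                x = dim.upper - _OPEN_EPS
        values[dim.name] = x

    return RFConfig(
        n_trees=int(values.get("n_trees", 100)),
        max_depth=int(values.get("max_depth", 10)),
        p_features=float(values.get("p_features", 0.5)),
    )


def space_from_yaml(source: str) -> HyperparameterSpace:
    """Build a space from a YAML document (path or literal text).

    Expected layout::

        dims:
          - {name: n_trees, kind: integer, lower: 50, upper: 200}
          - {name: p_features, kind: continuous, lower: 0.3, upper: 0.8,
             lower_open: true}
    """
    try:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    except (OSError, ValueError):
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict) or "dims" not in doc:
        raise ValueError("YAML space definition must contain a 'dims' list")
    dims = []
    for entry in doc["dims"]:
        dims.append(
            Dimension(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                lower=float(entry["lower"]),
                upper=float(entry["upper"]),
                lower_open=bool(entry.get("lower_open", False)),
                upper_open=bool(entry.get("upper_open", False)),
            )
        )
    return HyperparameterSpace(dims=tuple(dims))
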