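"""Relational-indeterminate computing kernel.

The basic object is a finite relation between ``n_args`` arguments and
``n_levels`` discrete values, stored as a dense boolean incidence table.
Three operations act on relations:

* :func:`abstraction` (cell-wise OR) — the memory-write primitive,
* :func:`containment` (cell-wise material implication) — the recognition
  primitive, optionally relaxed by a tolerated count of failing columns,
* :func:`reduction` — constructive retrieval: for a contained cue, pick one
  marked level per argument at random, centred on the cue.

A relation's *computational entropy* is the mean over arguments of
``log2`` of the number of marked levels, zero for (partial) functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Relation",
    "DiscreteFunction",
    "ReductionPolicy",
    "GeometryError",
    "abstraction",
    "containment",
    "reduction",
    "entropy",
    "function_to_relation",
    "relation_to_function",
    "relax_from_percent",
    "relax_to_percent",
]


class GeometryError(ValueError):
    """Raised when two relations or functions do not share (n_args, n_levels)."""


def _check_geometry(a, b) -> None:
    if (a.n_args, a.n_levels) != (b.n_args, b.n_levels):
        raise GeometryError(
            f"geometry mismatch: ({a.n_args}, {a.n_levels}) vs "
            f"({b.n_args}, {b.n_levels})"
        )


class Relation:
    """Dense boolean incidence table over ``n_args`` columns × ``n_levels`` rows.

    ``cell(i, v)`` is true iff argument ``i`` is related to level ``v``.
    The geometry is immutable after construction; the cell table is owned
    by the instance (inputs are copied).

    Parameters
    ----------
    n_args : int
        Number of argument columns (features), ≥ 1.
    n_levels : int
        Number of value rows (quantization levels), ≥ 1.
    cells : array-like of bool, shape (n_levels, n_args), optional
        Initial incidence; all-false when omitted.
    """

    __slots__ = ("_n_args", "_n_levels", "_cells")

    def __init__(self, n_args: int, n_levels: int, cells=None):
        if n_args < 1 or n_levels < 1:
            raise ValueError("n_args and n_levels must be positive")
        self._n_args = int(n_args)
        self._n_levels = int(n_levels)
        if cells is None:
            self._cells = np.zeros((self._n_levels, self._n_args), dtype=bool)
        else:
            arr = np.asarray(cells)
            if arr.shape != (self._n_levels, self._n_args):
                raise ValueError(
                    f"cells shape {arr.shape} != ({self._n_levels}, {self._n_args})"
                )
            if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
                raise ValueError("cells must be strictly boolean")
            self._cells = arr.astype(bool, copy=True)

    @property
    def n_args(self) -> int:
        return self._n_args

    @property
    def n_levels(self) -> int:
        return self._n_levels

    @property
    def cells(self) -> np.ndarray:
        """Read-only boolean view, shape (n_levels, n_args)."""
        v = self._cells.view()
        v.flags.writeable = False
        return v

    def cell(self, arg: int, level: int) -> bool:
        return bool(self._cells[level, arg])

    @classmethod
    def from_pairs(cls, n_args: int, n_levels: int, pairs) -> "Relation":
        """Build from an iterable of (argument, level) marks."""
        r = cls(n_args, n_levels)
        for i, v in pairs:
            r._cells[v, i] = True
        return r

    def pairs(self) -> set[tuple[int, int]]:
        """The set of (argument, level) marks; inverse of :meth:`from_pairs`."""
        levels, args = np.nonzero(self._cells)
        return set(zip(args.tolist(), levels.tolist()))

    def column_counts(self) -> np.ndarray:
        """Marked-level count μ_i per argument column."""
        return self._cells.sum(axis=0)

    def copy(self) -> "Relation":
        return Relation(self._n_args, self._n_levels, self._cells)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Relation):
            return NotImplemented
        return (
            self._n_args == other._n_args
            and self._n_levels == other._n_levels
            and bool(np.array_equal(self._cells, other._cells))
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Relation(n_args={self._n_args}, n_levels={self._n_levels}, "
            f"marks={int(self._cells.sum())})"
        )


class DiscreteFunction:
    """Partial mapping from argument index to one quantized level.

    Cues and retrieved objects on the bus are discrete functions; a function
    is a relation with at most one marked level per column, so it converts
    losslessly to a :class:`Relation`.

    Parameters
    ----------
    n_args, n_levels : int
        Shared geometry with the relations it interacts with.
    assignment : mapping int -> int, optional
        Argument index to level; omitted arguments are unassigned.
    """

    __slots__ = ("_n_args", "_n_levels", "_levels", "_assigned")

    def __init__(self, n_args: int, n_levels: int, assignment=None):
        if n_args < 1 or n_levels < 1:
            raise ValueError("n_args and n_levels must be positive")
        self._n_args = int(n_args)
        self._n_levels = int(n_levels)
        self._levels = np.zeros(self._n_args, dtype=np.int64)
        self._assigned = np.zeros(self._n_args, dtype=bool)
        if assignment is not None:
            for i, v in dict(assignment).items():
                self[i] = v

    @classmethod
    def from_arrays(cls, levels, assigned, n_levels: int) -> "DiscreteFunction":
        """Build from a level array plus an assigned mask (no copy semantics exposed)."""
        levels = np.asarray(levels, dtype=np.int64)
        assigned = np.asarray(assigned, dtype=bool)
        if levels.shape != assigned.shape or levels.ndim != 1:
            raise ValueError("levels and assigned must be 1-D and same length")
        f = cls(levels.size, n_levels)
        ok = assigned & (levels >= 0) & (levels < n_levels)
        if not np.array_equal(ok, assigned):
            raise ValueError("assigned level out of range")
        f._levels[assigned] = levels[assigned]
        f._assigned = assigned.copy()
        return f

    @property
    def n_args(self) -> int:
        return self._n_args

    @property
    def n_levels(self) -> int:
        return self._n_levels

    @property
    def levels(self) -> np.ndarray:
        """Level per argument (meaningful only where :attr:`assigned`)."""
        v = self._levels.view()
        v.flags.writeable = False
        return v

    @property
    def assigned(self) -> np.ndarray:
        v = self._assigned.view()
        v.flags.writeable = False
        return v

    def __getitem__(self, i: int) -> Optional[int]:
        return int(self._levels[i]) if self._assigned[i] else None

    def __setitem__(self, i: int, level: int) -> None:
        if not 0 <= level < self._n_levels:
            raise ValueError(f"level {level} outside [0, {self._n_levels - 1}]")
        self._levels[i] = level
        self._assigned[i] = True

    def items(self):
        for i in np.nonzero(self._assigned)[0]:
            yield int(i), int(self._levels[i])

    def n_assigned(self) -> int:
        return int(self._assigned.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiscreteFunction):
            return NotImplemented
        if (self._n_args, self._n_levels) != (other._n_args, other._n_levels):
            return False
        if not np.array_equal(self._assigned, other._assigned):
            return False
        m = self._assigned
        return bool(np.array_equal(self._levels[m], other._levels[m]))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"DiscreteFunction(n_args={self._n_args}, n_levels={self._n_levels}, "
            f"assigned={self.n_assigned()})"
        )


@dataclass
class ReductionPolicy:
    """How β selects one level per argument among a relation's marked levels.

    ``identity`` keeps the cue's level when it is marked (falling back to the
    nearest marked level otherwise); ``triangular`` samples with a triangular
    kernel peaking at the cue. All randomness flows from ``seed``; no global
    random state is touched.
    """

    mode: str = "identity"
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.mode not in ("identity", "triangular"):
            raise ValueError(f"mode must be 'identity' or 'triangular', got {self.mode!r}")
        self._rng = np.random.default_rng(self.seed)

    @property
    def rng(self) -> np.random.Generator:
        return self._rng


def abstraction(r_f: Relation, r_a: Relation) -> Relation:
    """λ(r_f, r_a): cell-wise OR (set union of marks). Inputs are unmodified."""
    _check_geometry(r_f, r_a)
    return Relation(r_f.n_args, r_f.n_levels, r_f.cells | r_a.cells)


def containment(r_a: Relation, r_f: Relation, relax: int = 0) -> tuple[bool, int]:
    """η(r_a, r_f): does every mark of r_a appear in r_f?

    Returns ``(accept, failed_args)`` where ``failed_args`` counts argument
    columns holding at least one mark of ``r_a`` absent from ``r_f``, and
    ``accept`` is ``failed_args <= relax``. With ``relax=0`` this is exactly
    material implication over all cells; unmarked cue columns constrain
    nothing (vacuous containment).
    """
    _check_geometry(r_a, r_f)
    if relax < 0:
        raise ValueError("relax must be non-negative")
    violating = r_a.cells & ~r_f.cells
    failed = int(violating.any(axis=0).sum())
    return failed <= relax, failed


def _column_center(cue_level: Optional[int], marked: np.ndarray) -> int:
    """Kernel center: the cue level, or the median marked level for a blank cue."""
    if cue_level is not None:
        return cue_level
    return int(np.median(marked))


def reduction(
    f_a: DiscreteFunction,
    r_f: Relation,
    policy: ReductionPolicy | None = None,
    relax: int = 0,
) -> Optional[DiscreteFunction]:
    """β(f_a, r_f): constructive retrieval centred on the cue.

    Returns ``None`` (a rejection value, never an exception) when the cue is
    not contained in ``r_f`` at the given ``relax``. Otherwise, per argument
    with a non-empty marked set S_i:

    * identity mode returns the cue's level when it lies in S_i, else the
      nearest member of S_i (ties toward the lower level);
    * triangular mode samples v ∈ S_i with weight ``d_max + 1 − |v − c|``
      where c is the cue's level (median of S_i for a blank cue) and
      ``d_max = max |v − c|`` — strictly positive on every candidate,
      peaked at the cue, exact identity when |S_i| = 1.

    Arguments with an empty S_i are unassigned in the result; every assigned
    output level is a member of its column's S_i.
    """
    _check_geometry(f_a, r_f)
    if policy is None:
        policy = ReductionPolicy()
    accept, _ = containment(function_to_relation(f_a), r_f, relax=relax)
    if not accept:
        return None

    out = DiscreteFunction(r_f.n_args, r_f.n_levels)
    cells = r_f.cells
    for i in range(r_f.n_args):
        marked = np.nonzero(cells[:, i])[0]
        if marked.size == 0:
            continue
        c = _column_center(f_a[i], marked)
        if policy.mode == "identity":
            # nearest marked level to the center; argmin takes the lower on ties
            out[i] = int(marked[np.argmin(np.abs(marked - c))])
        else:
            d = np.abs(marked - c)
            w = d.max() + 1 - d
            out[i] = int(policy.rng.choice(marked, p=w / w.sum()))
    return out


def entropy(r: Relation) -> float:
    """Computational entropy e(r) in bits.

    Mean over arguments of log2(μ_i), μ_i the marked-level count of column i;
    unmarked columns contribute zero (the ν_i = 1 convention for partial
    relations). Zero for any (partial) function; at most log2(n_levels).
    """
    mu = r.column_counts().astype(float)
    bits = np.where(mu >= 1, np.log2(np.maximum(mu, 1.0)), 0.0)
    return float(bits.mean())


def function_to_relation(f: DiscreteFunction) -> Relation:
    """Diagrammatic write: one mark per assigned argument."""
    r = Relation(f.n_args, f.n_levels)
    cells = np.zeros((f.n_levels, f.n_args), dtype=bool)
    idx = np.nonzero(f.assigned)[0]
    cells[f.levels[idx], idx] = True
    return Relation(f.n_args, f.n_levels, cells)


def relax_from_percent(percent: float, n_args: int) -> int:
    """Tolerated failing-column count for a percentage of features (floored)."""
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    return int(np.floor(percent / 100 * n_args))


def relax_to_percent(relax: int, n_args: int) -> float:
    """Relaxation count as a percentage of features, to one decimal
    (1 of 64 -> 1.6, 2 -> 3.1, 3 -> 4.7)."""
    return round(100 * relax / n_args, 1)


def relation_to_function(r: Relation) -> DiscreteFunction:
    """Inverse extraction; requires ≤ 1 mark per column."""
    counts = r.column_counts()
    if (counts > 1).any():
        bad = int(np.nonzero(counts > 1)[0][0])
        raise ValueError(f"column {bad} has {int(counts[bad])} marks; not a function")
    f = DiscreteFunction(r.n_args, r.n_levels)
    levels, args = np.nonzero(r.cells)
    for i, v in zip(args, levels):
        f[int(i)] = int(v)
    return f
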