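"""The associative memory proper: a bank of labelled registers.

Each register is a boolean relation of shared geometry n_features × 2**m
holding the disjunctive abstraction (union) of every instance registered
under its label. Recognition tests containment of the quantized cue in
every register; retrieval applies constructive reduction in the accepting
register of minimal entropy. A cue accepted by no register is rejected —
rejection is a value, never an exception.

`EntropicAssociativeMemory` is the scikit-learn-style estimator surface;
`memory_register` / `memory_recognize` / `memory_retrieve` are thin
functional wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import ric
from .quantization import LevelQuantizer
from .ric import DiscreteFunction, ReductionPolicy, Relation

__all__ = [
    "AssociativeRegister",
    "RecognitionReport",
    "EntropicAssociativeMemory",
    "memory_register",
    "memory_recognize",
    "memory_retrieve",
    "save_bank",
    "load_bank",
]

BANK_FORMAT_VERSION = 1


@dataclass
class AssociativeRegister:
    """One labelled n × 2**m table plus its registration count.

    ``label`` is a class identifier, or a tuple of identifiers for a
    register holding several overlapped classes.
    """

    label: object
    table: Relation
    registered_count: int = 0

    def register(self, f: DiscreteFunction) -> None:
        self.table = ric.abstraction(self.table, ric.function_to_relation(f))
        self.registered_count += 1
        self._entropy = None

    def entropy(self) -> float:
        # cached: the table only changes through register()
        if getattr(self, "_entropy", None) is None:
            self._entropy = ric.entropy(self.table)
        return self._entropy

    def matches(self, label) -> bool:
        """Does this register hold `label` (directly or inside a tuple label)?"""
        if self.label == label:
            return True
        return isinstance(self.label, tuple) and label in self.label


@dataclass
class RecognitionReport:
    """Per-register accept/failed/entropy plus the system verdict for one cue."""

    labels: list = field(default_factory=list)
    accept: np.ndarray = None
    failed_args: np.ndarray = None
    entropies: np.ndarray = None

    @property
    def system_accept(self) -> bool:
        return bool(self.accept.any())

    @property
    def accepting_labels(self) -> list:
        return [lab for lab, a in zip(self.labels, self.accept) if a]

    def best_label(self):
        """Accepting label of minimal entropy; ties break by bank order.

        Returns None on rejection.
        """
        if not self.system_accept:
            return None
        idx = np.nonzero(self.accept)[0]
        return self.labels[idx[np.argmin(self.entropies[idx])]]


class EntropicAssociativeMemory(BaseEstimator):
    """Bank of associative registers over quantized real features.

    Registration is `fit` / `partial_fit`: each (vector, label) pair is
    quantized and OR-ed into its register's table. `predict` recognizes each
    cue against every register and returns the accepting label of minimal
    entropy, or None for a rejected cue. `retrieve` additionally synthesizes
    a novel feature vector from the selected register via reduction.

    Parameters
    ----------
    m_bits : int, default=5
        Quantization bit depth; registers have 2**m_bits rows.
    relax : int, default=0
        Tolerated count of feature columns allowed to fail containment
        before a cue is rejected; applied uniformly to recognition and
        retrieval.
    quantizer : LevelQuantizer or None, default=None
        A pre-fitted quantizer to freeze (the usual staging: ranges fit on
        a training split, registration on a remembered split). When None,
        `fit` fits one on its own input.
    class_groups : sequence of tuples or None, default=None
        Optional grouping of class labels into overlapped registers, e.g.
        ``[(0, 1), (2, 3)]``. Default: one register per distinct label.

    Attributes
    ----------
    registers_ : list of AssociativeRegister, in fixed bank order.
    classes_ : ndarray of distinct labels seen.
    quantizer_ : the frozen LevelQuantizer.
    n_features_in_ : int
    """

    def __init__(self, m_bits: int = 5, relax: int = 0, quantizer=None,
                 class_groups=None):
        self.m_bits = m_bits
        self.relax = relax
        self.quantizer = quantizer
        self.class_groups = class_groups

    # --- construction -----------------------------------------------------------

    def _init_bank(self, X, classes) -> None:
        if self.relax < 0:
            raise ValueError("relax must be non-negative")
        if self.quantizer is not None:
            q = self.quantizer
            if q.m_bits != self.m_bits:
                raise ValueError("quantizer m_bits does not match the bank's m_bits")
        else:
            q = LevelQuantizer(m_bits=self.m_bits).fit(X)
        self.quantizer_ = q
        self.n_features_in_ = q.n_features_in_
        # plain python labels: registers serialize to JSON
        classes = sorted(
            (c.item() if isinstance(c, np.generic) else c for c in classes), key=str
        )
        self.classes_ = np.asarray(classes)
        if self.class_groups is not None:
            labels = [tuple(g) if len(g) > 1 else g[0] for g in self.class_groups]
            covered = {c for g in self.class_groups for c in g}
            missing = set(classes) - covered
            if missing:
                raise ValueError(f"class_groups does not cover classes {sorted(missing, key=str)}")
        else:
            labels = classes
        geom = (self.n_features_in_, self.quantizer_.n_levels)
        self.registers_ = [
            AssociativeRegister(lab, Relation(*geom)) for lab in labels
        ]
        self._by_label = {}
        for reg in self.registers_:
            for c in (reg.label if isinstance(reg.label, tuple) else (reg.label,)):
                self._by_label[c] = reg

    def fit(self, X, y):
        """Create the bank and register every (vector, label) pair."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self._init_bank(X, np.unique(y))
        return self.partial_fit(X, y)

    def partial_fit(self, X, y, classes=None):
        """Register additional instances into an existing (or new) bank."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not hasattr(self, "registers_"):
            self._init_bank(X, np.unique(y) if classes is None else classes)
        for v, lab in zip(X, y):
            self.register_one(v, lab)
        return self

    def register_one(self, v, label) -> None:
        """Register a single real vector under `label` (must exist in the bank)."""
        reg = self._by_label.get(label)
        if reg is None:
            raise KeyError(f"unknown label {label!r}")
        reg.register(self.quantizer_.to_function(np.asarray(v, dtype=float)))

    # --- recognition / retrieval ------------------------------------------------

    def _check_vector(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.n_features_in_,):
            raise ValueError(
                f"expected a vector of {self.n_features_in_} features, got shape {v.shape}"
            )
        return v

    def recognize_one(self, v) -> RecognitionReport:
        """Containment of the quantized cue against every register.

        Exactly one containment evaluation per register — rejection costs
        O(bank size), with no iteration.
        """
        cue = ric.function_to_relation(
            self.quantizer_.to_function(self._check_vector(v))
        )
        accept = np.zeros(len(self.registers_), dtype=bool)
        failed = np.zeros(len(self.registers_), dtype=np.int64)
        ent = np.zeros(len(self.registers_), dtype=float)
        for k, reg in enumerate(self.registers_):
            accept[k], failed[k] = ric.containment(cue, reg.table, relax=self.relax)
            ent[k] = reg.entropy()
        return RecognitionReport(
            labels=[r.label for r in self.registers_],
            accept=accept, failed_args=failed, entropies=ent,
        )

    def recognize(self, X) -> list[RecognitionReport]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return [self.recognize_one(v) for v in X]

    def predict(self, X) -> np.ndarray:
        """Minimal-entropy accepting label per cue; None marks rejection."""
        return np.asarray(
            [r.best_label() for r in self.recognize(X)], dtype=object
        )

    def retrieve_one(self, v, policy: ReductionPolicy | None = None):
        """Constructive retrieval: (label, retrieved real vector) or (None, None).

        The accepting register of minimal entropy is selected; reduction is
        applied to the quantized cue and the result dequantized.
        """
        if policy is None:
            policy = ReductionPolicy()
        report = self.recognize_one(v)
        label = report.best_label()
        if label is None:
            return None, None
        reg = self.registers_[report.labels.index(label)]
        cue = self.quantizer_.to_function(self._check_vector(v))
        out = ric.reduction(cue, reg.table, policy=policy, relax=self.relax)
        # containment already held, so reduction is defined
        return label, self.quantizer_.from_function(out)

    def retrieve(self, X, policy: ReductionPolicy | None = None):
        """Batch retrieval: (object array of labels/None, 2-D array, NaN rows on rejection)."""
        if policy is None:
            policy = ReductionPolicy()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        labels = np.empty(X.shape[0], dtype=object)
        out = np.full_like(X, np.nan, dtype=float)
        for j, v in enumerate(X):
            lab, rv = self.retrieve_one(v, policy)
            labels[j] = lab
            if rv is not None:
                out[j] = rv
        return labels, out

    def register_entropies(self) -> np.ndarray:
        return np.asarray([r.entropy() for r in self.registers_])

    # --- persistence ------------------------------------------------------------

    def to_dict(self) -> dict:
        q = self.quantizer_
        return {
            "version": BANK_FORMAT_VERSION,
            "n_features": int(self.n_features_in_),
            "m_bits": int(self.m_bits),
            "quantizer": {"lo": q.lo_.tolist(), "hi": q.hi_.tolist()},
            "relax": int(self.relax),
            "registers": [
                {
                    "label": list(r.label) if isinstance(r.label, tuple) else r.label,
                    "registered_count": int(r.registered_count),
                    "rows": r.table.cells.astype(int).tolist(),
                }
                for r in self.registers_
            ],
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "EntropicAssociativeMemory":
        for key in ("n_features", "m_bits", "quantizer", "relax", "registers"):
            if key not in d:
                raise ValueError(f"bank file missing field {key!r}")
        n = int(d["n_features"])
        m = int(d["m_bits"])
        qd = d["quantizer"]
        lo, hi = np.asarray(qd["lo"], float), np.asarray(qd["hi"], float)
        if lo.shape != (n,) or hi.shape != (n,):
            raise ValueError("quantizer lo/hi length does not match n_features")
        q = LevelQuantizer(m_bits=m)
        q.lo_, q.hi_, q.n_features_in_ = lo, hi, n

        bank = cls(m_bits=m, relax=int(d["relax"]), quantizer=q)
        bank.quantizer_ = q
        bank.n_features_in_ = n
        bank.registers_ = []
        n_levels = 2 ** m
        for rd in d["registers"]:
            label = tuple(rd["label"]) if isinstance(rd["label"], list) else rd["label"]
            rows = np.asarray(rd["rows"])
            if rows.shape != (n_levels, n):
                raise ValueError(
                    f"register {label!r}: rows shape {rows.shape} != ({n_levels}, {n})"
                )
            bank.registers_.append(
                AssociativeRegister(
                    label, Relation(n, n_levels, rows), int(rd["registered_count"])
                )
            )
        bank._by_label = {}
        for reg in bank.registers_:
            for c in (reg.label if isinstance(reg.label, tuple) else (reg.label,)):
                bank._by_label[c] = reg
        flat = sorted({c for r in bank.registers_
                       for c in (r.label if isinstance(r.label, tuple) else (r.label,))},
                      key=str)
        bank.classes_ = np.asarray(flat)
        return bank

    @classmethod
    def load(cls, path) -> "EntropicAssociativeMemory":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EntropicAssociativeMemory):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# --- functional wrappers ---------------------------------------------------------

def memory_register(bank: EntropicAssociativeMemory, f, label) -> EntropicAssociativeMemory:
    bank.register_one(f, label)
    return bank


def memory_recognize(bank: EntropicAssociativeMemory, f) -> RecognitionReport:
    return bank.recognize_one(f)


def memory_retrieve(bank: EntropicAssociativeMemory, f,
                    policy: ReductionPolicy | None = None):
    return bank.retrieve_one(f, policy)


def save_bank(bank: EntropicAssociativeMemory, path) -> None:
    bank.save(path)


def load_bank(path) -> EntropicAssociativeMemory:
    return EntropicAssociativeMemory.load(path)
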