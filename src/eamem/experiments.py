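"""Metrics and desk-scale analogues of the five memory experiments.

Each runner generates (or receives) a synthetic corpus, stages it through
the train/rem/test splits — quantizer ranges frozen on the train split,
registers filled from the remembered split, evaluation on the test split —
and emits one metrics row per grid point:

1. granularity sweep m = 0..9 for ten single-class registers;
2. the same sweep with overlapped two-class registers;
3. fill-fraction sweep 1..100% of the remembered split at fixed geometry;
4. cue-retrieval similarity under the triangular policy versus entropy;
5. recognition of occluded cues with relaxation 0..3 of 64 features.

The published curves for these experiments depend on an image corpus and a
trained encoder, so they are reproduced here as monotonicity and ordering
properties at desk scale, not as point values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .datasets import (DEFAULT_FRACTIONS, GeneratorConfig, feature_columns,
                       generate_corpus, occlude, partition)
from .memory import EntropicAssociativeMemory, RecognitionReport
from .quantization import LevelQuantizer
from .ric import ReductionPolicy

__all__ = [
    "MetricsRow",
    "per_register_metrics",
    "system_metrics",
    "similarity",
    "run_experiment1",
    "run_experiment2",
    "run_experiment3",
    "run_experiment4",
    "run_experiment5",
]

DEFAULT_PAIRING = ((0, 1), (2, 3), (4, 5), (6, 7), (8, 9))
DEFAULT_FILL_PERCENTS = (1, 2, 4, 8, 16, 32, 64, 100)


@dataclass
class MetricsRow:
    """One grid point of an experiment run; precisions/recalls in [0, 1]."""

    experiment: str
    m_bits: int
    fill_fraction: float = 1.0
    relax: int = 0
    occlusion: str = "none"
    mean_precision: float = np.nan
    mean_recall: float = np.nan
    mean_entropy: float = np.nan
    system_precision: float = np.nan
    system_recall: float = np.nan
    mean_accepting: float = np.nan
    mean_similarity: float = np.nan
    rejection_rate: float = np.nan
    all_rejected: bool = False


def _register_positive(reg_label, true_label) -> bool:
    if isinstance(reg_label, tuple):
        return true_label in reg_label
    return reg_label == true_label


def per_register_metrics(reports: list[RecognitionReport], true_labels,
                         average: str = "macro") -> tuple[float, float]:
    """Treat each register as a binary accept/reject classifier.

    Positives of register k are the instances whose true label the register
    holds. Precision is 1.0 for a register that accepts nothing (no false
    positives were produced); macro averaging is unweighted over registers,
    micro pools the counts.
    """
    if not reports:
        raise ValueError("empty test set")
    labels = reports[0].labels
    true_labels = np.asarray(true_labels)
    accept = np.stack([r.accept for r in reports])          # (n_inst, n_reg)
    positive = np.stack([
        [_register_positive(lab, t) for lab in labels] for t in true_labels
    ])
    tp = (accept & positive).sum(axis=0).astype(float)
    fp = (accept & ~positive).sum(axis=0).astype(float)
    fn = (~accept & positive).sum(axis=0).astype(float)
    if average == "micro":
        tp, fp, fn = tp.sum(), fp.sum(), fn.sum()
        precision = tp / (tp + fp) if tp + fp > 0 else 1.0
        recall = tp / (tp + fn) if tp + fn > 0 else 1.0
        return float(precision), float(recall)
    if average != "macro":
        raise ValueError("average must be 'macro' or 'micro'")
    with np.errstate(invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 1.0)
    return float(precision.mean()), float(recall.mean())


def system_metrics(decisions, true_labels) -> tuple[float, float, bool]:
    """Precision over non-rejected cues, recall over all cues.

    A decision is the selected register's label (possibly a tuple of
    overlapped classes) or None for rejection; it is correct when it holds
    the true label. When every cue is rejected, precision is reported as
    1.0 with the `all_rejected` flag set, keeping the precision/recall
    trade-off well defined at extreme settings.
    """
    true_labels = np.asarray(true_labels)
    decisions = list(decisions)
    if len(decisions) != len(true_labels):
        raise ValueError("one decision per instance required")
    answered = np.asarray([d is not None for d in decisions])
    correct = np.asarray([
        d is not None and _register_positive(d, t)
        for d, t in zip(decisions, true_labels)
    ])
    recall = float(correct.sum() / len(decisions))
    if not answered.any():
        return 1.0, recall, True
    return float(correct.sum() / answered.sum()), recall, False


def similarity(cue, retrieved, q: LevelQuantizer) -> float:
    """1 − mean normalized absolute difference over mutually assigned features.

    Differences are scaled by each feature's fitted range; degenerate
    (zero-width) features are skipped. NaN when no feature is mutually
    assigned.
    """
    cue = np.asarray(cue, dtype=float)
    retrieved = np.asarray(retrieved, dtype=float)
    span = q.hi_ - q.lo_
    both = ~np.isnan(cue) & ~np.isnan(retrieved) & (span > 0)
    if not both.any():
        return float("nan")
    d = np.abs(cue[both] - retrieved[both]) / span[both]
    return float(1.0 - d.mean())


# --- shared pipeline -------------------------------------------------------------

def _staged_splits(cfg: GeneratorConfig, fold: int = 0):
    corpus = partition(generate_corpus(cfg), cfg.fractions, fold=fold,
                       seed=cfg.seed + 1)
    cols = feature_columns(corpus)
    out = {}
    for name in ("train", "rem", "test"):
        part = corpus[corpus["split"] == name]
        out[name] = (part[cols].to_numpy(float), part["label"].to_numpy())
    return out


def _decide(reports, selection: str, rng: np.random.Generator | None):
    """Per-cue label decision: minimal-entropy acceptor, or uniform-random acceptor."""
    if selection == "min_entropy":
        return [r.best_label() for r in reports]
    if selection != "random":
        raise ValueError("selection must be 'min_entropy' or 'random'")
    decisions = []
    for r in reports:
        accepted = r.accepting_labels
        decisions.append(
            accepted[int(rng.integers(len(accepted)))] if accepted else None
        )
    return decisions


def _evaluate(bank: EntropicAssociativeMemory, X, y, *, experiment: str,
              selection: str = "min_entropy", rng=None,
              average: str = "macro", **row_kwargs) -> MetricsRow:
    reports = bank.recognize(X)
    mp, mr = per_register_metrics(reports, y, average=average)
    decisions = _decide(reports, selection, rng)
    sp, sr, flag = system_metrics(decisions, y)
    return MetricsRow(
        experiment=experiment,
        m_bits=int(bank.m_bits),
        relax=int(bank.relax),
        mean_precision=mp,
        mean_recall=mr,
        mean_entropy=float(bank.register_entropies().mean()),
        system_precision=sp,
        system_recall=sr,
        mean_accepting=float(np.mean([r.accept.sum() for r in reports])),
        rejection_rate=float(np.mean([d is None for d in decisions])),
        all_rejected=flag,
        **row_kwargs,
    )


def _rows_to_frame(rows: list[MetricsRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])


# --- experiment runners ----------------------------------------------------------

def run_experiment1(cfg: GeneratorConfig | None = None, m_values=range(10),
                    fold: int = 0, selection: str = "min_entropy",
                    average: str = "macro") -> pd.DataFrame:
    """Granularity sweep: ten single-class registers of size n × 2**m, m = 0..9."""
    cfg = cfg or GeneratorConfig()
    splits = _staged_splits(cfg, fold)
    (Xtr, _), (Xrem, yrem), (Xte, yte) = splits["train"], splits["rem"], splits["test"]
    rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for m in m_values:
        q = LevelQuantizer(m_bits=m).fit(Xtr)
        bank = EntropicAssociativeMemory(m_bits=m, quantizer=q).fit(Xrem, yrem)
        rows.append(_evaluate(bank, Xte, yte, experiment="exp1",
                              selection=selection, rng=rng, average=average))
    return _rows_to_frame(rows)


def run_experiment2(cfg: GeneratorConfig | None = None,
                    pairing=DEFAULT_PAIRING, m_values=range(10),
                    fold: int = 0) -> pd.DataFrame:
    """Overlapped registers: each holds two classes; otherwise as experiment 1."""
    cfg = cfg or GeneratorConfig()
    splits = _staged_splits(cfg, fold)
    (Xtr, _), (Xrem, yrem), (Xte, yte) = splits["train"], splits["rem"], splits["test"]
    rows = []
    for m in m_values:
        q = LevelQuantizer(m_bits=m).fit(Xtr)
        bank = EntropicAssociativeMemory(
            m_bits=m, quantizer=q, class_groups=pairing).fit(Xrem, yrem)
        rows.append(_evaluate(bank, Xte, yte, experiment="exp2"))
    return _rows_to_frame(rows)


def _incremental_fill_banks(cfg, fold, m_bits, fill_percents, relax=0,
                            class_groups=None):
    """Yield (percent, bank) with the bank filled by the first p% of the
    remembered split per class, in one fixed seeded order (cumulative)."""
    splits = _staged_splits(cfg, fold)
    (Xtr, _), (Xrem, yrem) = splits["train"], splits["rem"]
    q = LevelQuantizer(m_bits=m_bits).fit(Xtr)
    bank = EntropicAssociativeMemory(m_bits=m_bits, relax=relax, quantizer=q,
                                     class_groups=class_groups)
    rng = np.random.default_rng(cfg.seed + 3)
    per_class = {}
    for lab in np.unique(yrem):
        idx = np.nonzero(yrem == lab)[0]
        per_class[lab] = rng.permutation(idx)
    bank.partial_fit(Xrem[:0], yrem[:0], classes=np.unique(yrem))
    done = {lab: 0 for lab in per_class}
    for pct in fill_percents:
        for lab, order in per_class.items():
            upto = int(np.floor(pct / 100 * len(order)))
            new = order[done[lab]:upto]
            if new.size:
                bank.partial_fit(Xrem[new], yrem[new])
            done[lab] = max(done[lab], upto)
        yield pct, bank, splits


def run_experiment3(cfg: GeneratorConfig | None = None,
                    fill_percents=DEFAULT_FILL_PERCENTS,
                    m_bits: int = 5, fold: int = 0) -> pd.DataFrame:
    """Fill-fraction sweep at fixed 2**m-row geometry (default 32 rows)."""
    cfg = cfg or GeneratorConfig()
    rows = []
    for pct, bank, splits in _incremental_fill_banks(cfg, fold, m_bits, fill_percents):
        Xte, yte = splits["test"]
        rows.append(_evaluate(bank, Xte, yte, experiment="exp3",
                              fill_fraction=pct / 100))
    return _rows_to_frame(rows)


def run_experiment4(cfg: GeneratorConfig | None = None,
                    fill_percents=DEFAULT_FILL_PERCENTS, m_bits: int = 5,
                    fold: int = 0, policy_seed: int = 11) -> pd.DataFrame:
    """Cue-retrieval similarity under the triangular policy versus entropy."""
    cfg = cfg or GeneratorConfig()
    rows = []
    for pct, bank, splits in _incremental_fill_banks(cfg, fold, m_bits, fill_percents):
        Xte, yte = splits["test"]
        policy = ReductionPolicy("triangular", seed=policy_seed)
        sims = []
        for v in Xte:
            lab, rv = bank.retrieve_one(v, policy)
            if lab is not None:
                sims.append(similarity(v, rv, bank.quantizer_))
        row = _evaluate(bank, Xte, yte, experiment="exp4", fill_fraction=pct / 100)
        row.mean_similarity = float(np.nanmean(sims)) if sims else np.nan
        rows.append(row)
    return _rows_to_frame(rows)


def run_experiment5(cfg: GeneratorConfig | None = None,
                    relax_values=(0, 1, 2, 3),
                    occlusions=(("prefix", 0.05), ("bars", 0.05)),
                    mode: str = "background", m_bits: int = 5,
                    fold: int = 0) -> pd.DataFrame:
    """Occluded-cue recognition with relaxed containment.

    Occlusion is emulated in feature space: a fraction of features is
    replaced by background draws from the pooled all-class marginal
    (``mode="background"``, the default — missing-mode occlusion interacts
    with vacuous containment and accepts everything) or marked missing.
    The default fraction corrupts 3 of 64 features: heavy pixel occlusion
    reaches the registers only through the encoder, which reconstructs most
    abstract features, so the feature-level damage is on the same scale as
    the 1–3-feature relaxation sweep that probes it.
    """
    cfg = cfg or GeneratorConfig()
    splits = _staged_splits(cfg, fold)
    (Xtr, _), (Xrem, yrem), (Xte, yte) = splits["train"], splits["rem"], splits["test"]
    q = LevelQuantizer(m_bits=m_bits).fit(Xtr)
    rows = []
    for pattern, fraction in occlusions:
        Xocc = np.stack([
            occlude(v, mode=mode, fraction=fraction, pattern=pattern,
                    seed=cfg.seed + 5 + j, pool=Xrem)
            for j, v in enumerate(Xte)
        ])
        bank = EntropicAssociativeMemory(m_bits=m_bits, quantizer=q).fit(Xrem, yrem)
        for relax in relax_values:
            bank.relax = relax
            rows.append(_evaluate(
                bank, Xocc, yte, experiment="exp5",
                occlusion=f"{pattern}:{fraction:g}"))
    return _rows_to_frame(rows)
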