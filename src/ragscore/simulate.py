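"""Synthetic study corpora with known ground truth.

Generates collections of datasets in which each gene belongs to one of four
true classes and each dataset reports a noisy subset of genes:

* ``true_upex``       — emits (expressed, up) calls
* ``true_downnd``     — emits (not_detected, down) calls
* ``background_expressed`` / ``background_absent`` — emit only a status call

Coverage is Bernoulli(``p_report``) per (gene, dataset); every emitted call is
independently flipped to its contradiction with probability ``p_flip``. All
randomness derives from a single seed via per-dataset substreams, so corpora
are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .genelists import (
    AliasMap,
    Call,
    Cohort,
    ConditionLabel,
    Corpus,
    DatasetRecord,
    GeneCall,
    Strategy,
    StudyMetadata,
)
from .rags import RAGResult

TRUE_UPEX = "true_upex"
TRUE_DOWNND = "true_downnd"
BACKGROUND_EXPRESSED = "background_expressed"
BACKGROUND_ABSENT = "background_absent"

CLASSES = (TRUE_UPEX, TRUE_DOWNND, BACKGROUND_EXPRESSED, BACKGROUND_ABSENT)

_RECEPTIVE = ConditionLabel.from_raw("receptive")
_PRE_RECEPTIVE = ConditionLabel.from_raw("pre-receptive")
_COMPARISON = (_RECEPTIVE, _PRE_RECEPTIVE)

#: The comparison string all simulated pattern calls are curated against.
SIM_COMPARISON = "receptive_vs_pre_receptive"


@dataclass(frozen=True)
class SimulationParams:
    n_genes: int
    n_datasets: int
    frac_true_upex: float = 0.1
    frac_true_downnd: float = 0.05
    frac_background_expressed: float = 0.6
    p_report: float = 0.8
    p_flip: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_datasets < 1:
            raise ValueError("n_genes and n_datasets must be >= 1")
        for name in ("frac_true_upex", "frac_true_downnd", "frac_background_expressed",
                     "p_report", "p_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_true_upex + self.frac_true_downnd > 1.0:
            raise ValueError("frac_true_upex + frac_true_downnd must be <= 1")


@dataclass
class SyntheticTruth:
    """Ground-truth class per gene, plus the parameters that generated it."""

    classes: dict[str, str] = field(default_factory=dict)
    params: SimulationParams = None  # type: ignore[assignment]

    def symbols_of(self, cls: str) -> set[str]:
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        return {s for s, c in self.classes.items() if c == cls}


def _assign_classes(params: SimulationParams) -> dict[str, str]:
    n = params.n_genes
    n_up = round(params.frac_true_upex * n)
    n_dn = min(round(params.frac_true_downnd * n), n - n_up)
    n_bg = n - n_up - n_dn
    n_bg_exp = round(params.frac_background_expressed * n_bg)
    symbols = [f"G{i:05d}" for i in range(n)]
    classes: dict[str, str] = {}
    for i, s in enumerate(symbols):
        if i < n_up:
            classes[s] = TRUE_UPEX
        elif i < n_up + n_dn:
            classes[s] = TRUE_DOWNND
        elif i < n_up + n_dn + n_bg_exp:
            classes[s] = BACKGROUND_EXPRESSED
        else:
            classes[s] = BACKGROUND_ABSENT
    return classes


def _true_calls(cls: str) -> tuple[Call, Union[Call, None]]:
    """(status call, pattern call or None) a gene of this class emits."""
    if cls == TRUE_UPEX:
        return Call.EXPRESSED, Call.UP
    if cls == TRUE_DOWNND:
        return Call.NOT_DETECTED, Call.DOWN
    if cls == BACKGROUND_EXPRESSED:
        return Call.EXPRESSED, None
    return Call.NOT_DETECTED, None


def simulate_corpus(params: SimulationParams) -> tuple[Corpus, SyntheticTruth]:
    """Generate a corpus and its ground truth; reproducible from ``params.seed``."""
    classes = _assign_classes(params)
    symbols = list(classes)
    datasets = []
    for d_idx in range(params.n_datasets):
        # per-dataset substream: independent of n_datasets and of other streams
        rng = np.random.default_rng([params.seed, d_idx])
        dataset_id = f"SIM{d_idx:03d}"
        report = rng.random(len(symbols)) < params.p_report
        flip_status = rng.random(len(symbols)) < params.p_flip
        flip_pattern = rng.random(len(symbols)) < params.p_flip
        calls: list[GeneCall] = []
        for g_idx, symbol in enumerate(symbols):
            if not report[g_idx]:
                continue
            status, pattern = _true_calls(classes[symbol])
            if flip_status[g_idx]:
                status = status.opposite
            calls.append(
                GeneCall(
                    symbol=symbol,
                    call=status,
                    condition=_RECEPTIVE,
                    source_dataset=dataset_id,
                )
            )
            if pattern is not None:
                if flip_pattern[g_idx]:
                    pattern = pattern.opposite
                calls.append(
                    GeneCall(
                        symbol=symbol,
                        call=pattern,
                        comparison=_COMPARISON,
                        source_dataset=dataset_id,
                    )
                )
        datasets.append(
            DatasetRecord(
                dataset_id=dataset_id,
                metadata=StudyMetadata(
                    study_id=dataset_id,
                    sample_size=8,
                    strategy=Strategy.MICROARRAY,
                    platform="simulated",
                    cohort=Cohort.HEALTHY,
                ),
                condition=_RECEPTIVE,
                calls=calls,
            )
        )
    corpus = Corpus(
        datasets=datasets,
        alias_map=AliasMap(),
        provenance=f"simulated corpus (seed={params.seed})",
    )
    return corpus, SyntheticTruth(classes=classes, params=params)


def evaluate_recovery(result: RAGResult, truth: SyntheticTruth) -> dict[str, dict]:
    """Precision / recall / F1 of the classified sets against ground truth."""
    universe = set(truth.classes)
    predicted = {
        TRUE_UPEX: {e.symbol for e in result.up_ex},
        TRUE_DOWNND: {e.symbol for e in result.down_nd},
    }
    stray = (predicted[TRUE_UPEX] | predicted[TRUE_DOWNND]) - universe
    if stray:
        raise ValueError(f"result contains symbols outside the truth universe: {sorted(stray)[:5]}")
    metrics: dict[str, dict] = {}
    for cls, pred in predicted.items():
        actual = truth.symbols_of(cls)
        tp = len(pred & actual)
        fp = len(pred - actual)
        fn = len(actual - pred)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall)
            else 0.0
        )
        metrics[cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "tp": tp,
            "fp": fp,
            "fn": fn,
        }
    return metrics


def survival_probability(p_flip: float, n_reports: int) -> float:
    """Closed-form P(a two-call gene keeps a contradiction-free record).

    A gene reported in ``k`` datasets emits ``2k`` independently flipped
    calls; it survives zero-contradiction classification iff none flip.
    """
    return (1.0 - p_flip) ** (2 * n_reports)
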