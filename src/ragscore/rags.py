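"""Derivation of consistently-behaving gene sets (Up-Ex / Down-Nd).

Up-Ex genes are consistently expressed and upregulated in the first condition
of the comparison; Down-Nd genes are consistently not detected and
downregulated. "Consistently" defaults to zero contradicting datasets: the
minimum printed cumulative score of 4 (one vote on each dimension) leaves no
room for averaging away disagreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .genelists import Cohort, Comparison, Corpus
from .scoring import GeneScoreCard, score_all

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RAGParams:
    """Classification thresholds and cohort filter."""

    min_status_datasets: int = 1
    min_pattern_datasets: int = 1
    require_zero_contradiction: bool = True
    cohorts_included: frozenset = frozenset({Cohort.HEALTHY})

    def __post_init__(self) -> None:
        if self.min_status_datasets < 1 or self.min_pattern_datasets < 1:
            raise ValueError("minimum dataset supports must be >= 1")
        object.__setattr__(
            self,
            "cohorts_included",
            frozenset(Cohort(c) for c in self.cohorts_included),
        )


@dataclass(frozen=True)
class RAGEntry:
    """One classified gene with its scores."""

    symbol: str
    pattern_score: int
    status_score: int
    cumulative: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cumulative != self.pattern_score + self.status_score:
            raise ValueError(
                f"{self.symbol}: cumulative {self.cumulative} != "
                f"{self.pattern_score} + {self.status_score}"
            )


@dataclass
class RAGResult:
    """Ranked Up-Ex and Down-Nd gene sets with provenance."""

    up_ex: list[RAGEntry] = field(default_factory=list)
    down_nd: list[RAGEntry] = field(default_factory=list)
    params: RAGParams = field(default_factory=RAGParams)
    corpus_digest: str = ""

    def __post_init__(self) -> None:
        overlap = {e.symbol for e in self.up_ex} & {e.symbol for e in self.down_nd}
        if overlap:
            raise ValueError(f"up_ex and down_nd overlap: {sorted(overlap)}")


def filter_datasets(corpus: Corpus, params: RAGParams) -> Corpus:
    """Keep only datasets whose cohort is included (healthy-only by default)."""
    kept = [d for d in corpus.datasets if d.metadata.cohort in params.cohorts_included]
    logger.info(
        "cohort filter: kept %d of %d datasets (cohorts=%s)",
        len(kept),
        len(corpus.datasets),
        sorted(c.value for c in params.cohorts_included),
    )
    if not kept:
        raise ValueError(
            "cohort filter removed every dataset "
            f"(included cohorts: {sorted(c.value for c in params.cohorts_included)})"
        )
    return Corpus(datasets=kept, alias_map=corpus.alias_map, provenance=corpus.provenance)


def _upex_qualifies(card: GeneScoreCard, params: RAGParams) -> bool:
    ok = (
        card.status.n_expressed >= params.min_status_datasets
        and card.pattern.n_up >= params.min_pattern_datasets
    )
    if params.require_zero_contradiction:
        ok = ok and card.status.n_not_detected == 0 and card.pattern.n_down == 0
    return ok


def _downnd_qualifies(card: GeneScoreCard, params: RAGParams) -> bool:
    ok = (
        card.status.n_not_detected >= params.min_status_datasets
        and card.pattern.n_down >= params.min_pattern_datasets
    )
    if params.require_zero_contradiction:
        ok = ok and card.status.n_expressed == 0 and card.pattern.n_up == 0
    return ok


def derive_rags(
    corpus: Corpus,
    comparison: Union[str, Comparison],
    params: Optional[RAGParams] = None,
    names: Optional[Mapping[str, str]] = None,
) -> RAGResult:
    """Classify genes into Up-Ex and Down-Nd sets.

    The corpus is cohort-filtered (idempotent if already filtered), scored,
    and classified. With ``require_zero_contradiction`` disabled a gene may
    qualify for both classes; the larger cumulative wins and ties are
    excluded, so the two sets stay disjoint.
    """
    params = params or RAGParams()
    filtered = filter_datasets(corpus, params)
    cards = score_all(filtered, comparison)
    names = names or {}

    up_cards: list[GeneScoreCard] = []
    down_cards: list[GeneScoreCard] = []
    for card in cards:
        up_ok = _upex_qualifies(card, params)
        down_ok = _downnd_qualifies(card, params)
        if up_ok and down_ok:
            # only reachable with require_zero_contradiction=False
            if card.cumulative_upex > card.cumulative_downnd:
                down_ok = False
            elif card.cumulative_downnd > card.cumulative_upex:
                up_ok = False
            else:
                up_ok = down_ok = False
        if up_ok:
            up_cards.append(card)
        if down_ok:
            down_cards.append(card)

    up_cards.sort(key=lambda c: (-c.cumulative_upex, -c.pattern.up_score, c.symbol))
    down_cards.sort(
        key=lambda c: (-c.cumulative_downnd, -c.pattern.down_score, c.symbol)
    )
    return RAGResult(
        up_ex=[
            RAGEntry(
                symbol=c.symbol,
                pattern_score=c.pattern.up_score,
                status_score=c.status.expressed_score,
                cumulative=c.cumulative_upex,
                name=names.get(c.symbol),
            )
            for c in up_cards
        ],
        down_nd=[
            RAGEntry(
                symbol=c.symbol,
                pattern_score=c.pattern.down_score,
                status_score=c.status.not_detected_score,
                cumulative=c.cumulative_downnd,
                name=names.get(c.symbol),
            )
            for c in down_cards
        ],
        params=params,
        corpus_digest=filtered.digest(),
    )


def derive_suboptimal(
    reference: RAGResult,
    case_corpus: Corpus,
    comparison: Union[str, Comparison],
) -> list[str]:
    """Reference Up-Ex genes whose behaviour in a case cohort contradicts
    their class: reported down or not detected at least once and never up.

    Returns an alphabetically ordered symbol list.
    """
    from .genelists import comparison_key, parse_comparison

    comp = parse_comparison(comparison)
    keys = {comparison_key(comp), comparison_key(comp)[::-1]}
    covered = any(
        c.comparison is not None and comparison_key(c.comparison) in keys
        for d in case_corpus.datasets
        for c in d.calls
    )
    if not covered:
        raise ValueError(
            f"comparison {comparison_key(comp)[0]}_vs_{comparison_key(comp)[1]} "
            "absent from case corpus"
        )
    cards = score_all(case_corpus, comp)
    by_symbol = {c.symbol: c for c in cards}
    out = []
    for entry in reference.up_ex:
        card = by_symbol.get(entry.symbol)
        if card is None:
            continue
        contradicted = card.pattern.n_down > 0 or card.status.n_not_detected > 0
        if contradicted and card.pattern.n_up == 0:
            out.append(entry.symbol)
    return sorted(out)


_EXPORT_HEADER = "s_no\tsymbol\tname\tpattern_score\tstatus_score\tcumulative_score\n"


def export_rag_tables(
    result: RAGResult,
    out_dir: Union[str, Path],
    names: Optional[Mapping[str, str]] = None,
) -> tuple[Path, Path]:
    """Write ranked ``up_ex.tsv`` and ``down_nd.tsv``; byte-stable across runs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = names or {}
    paths = (out_dir / "up_ex.tsv", out_dir / "down_nd.tsv")
    for path, entries in zip(paths, (result.up_ex, result.down_nd)):
        lines = [_EXPORT_HEADER]
        for i, e in enumerate(entries, start=1):
            name = e.name if e.name is not None else names.get(e.symbol, "")
            lines.append(
                f"{i}\t{e.symbol}\t{name}\t{e.pattern_score}\t{e.status_score}\t{e.cumulative}\n"
            )
        path.write_text("".join(lines), encoding="utf-8", newline="\n")
    return paths


def read_rag_table(path: Union[str, Path]) -> list[RAGEntry]:
    """Read one exported table back into entries (inverse of export)."""
    import csv

    rows = list(
        csv.DictReader(Path(path).read_text(encoding="utf-8").splitlines(), delimiter="\t")
    )
    return [
        RAGEntry(
            symbol=r["symbol"],
            name=r.get("name") or None,
            pattern_score=int(r["pattern_score"]),
            status_score=int(r["status_score"]),
            cumulative=int(r["cumulative_score"]),
        )
        for r in rows
    ]
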