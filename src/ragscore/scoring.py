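"""Reliability scoring: vote-counting consensus across curated datasets.

Every dataset that reports a gene with a given call contributes two points to
the corresponding score (one dataset = one vote = 2 points). Opposing calls
are scored separately — a gene seen expressed in three datasets and not
detected in two gets ``expressed_score = 6`` and ``not_detected_score = 4`` —
and disagreement is surfaced through a ``consistent`` flag rather than an
arithmetic penalty. The cumulative scores pair the status and pattern
dimensions:

* ``cumulative_upex   = up_score   + expressed_score``
* ``cumulative_downnd = down_score + not_detected_score``

Direction convention: "up" means higher in the *first*-named condition of the
comparison pair. Datasets curated against the reversed pair have their
pattern calls flipped at scoring time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .genelists import (
    KNOWN_CONDITIONS,
    Call,
    Comparison,
    ConditionLabel,
    Corpus,
    comparison_key,
    normalize_symbol,
    parse_comparison,
)

#: Points contributed by a single dataset vote.
VOTE_WEIGHT = 2


@dataclass(frozen=True)
class StatusScore:
    """Reliability of a gene's expressed / not-detected status in one condition."""

    symbol: str
    condition: ConditionLabel
    n_expressed: int
    n_not_detected: int

    @property
    def expressed_score(self) -> int:
        return VOTE_WEIGHT * self.n_expressed

    @property
    def not_detected_score(self) -> int:
        return VOTE_WEIGHT * self.n_not_detected

    @property
    def consistent(self) -> bool:
        """True iff exactly one of the two opposing counts is positive."""
        return (self.n_expressed > 0) != (self.n_not_detected > 0)


@dataclass(frozen=True)
class PatternScore:
    """Reliability of a gene's up / down regulation for one ordered comparison."""

    symbol: str
    comparison: Comparison
    n_up: int
    n_down: int

    @property
    def up_score(self) -> int:
        return VOTE_WEIGHT * self.n_up

    @property
    def down_score(self) -> int:
        return VOTE_WEIGHT * self.n_down

    @property
    def consistent(self) -> bool:
        return (self.n_up > 0) != (self.n_down > 0)


@dataclass(frozen=True)
class GeneScoreCard:
    """Joint status + pattern scores for one gene on one comparison."""

    symbol: str
    status: StatusScore
    pattern: PatternScore

    @property
    def cumulative_upex(self) -> int:
        return self.pattern.up_score + self.status.expressed_score

    @property
    def cumulative_downnd(self) -> int:
        return self.pattern.down_score + self.status.not_detected_score


def _resolve_condition(
    condition: Union[str, ConditionLabel], corpus: Corpus
) -> ConditionLabel:
    label = (
        condition
        if isinstance(condition, ConditionLabel)
        else ConditionLabel.from_raw(condition)
    )
    if label.canonical not in KNOWN_CONDITIONS:
        observed = {
            c.condition.canonical
            for d in corpus.datasets
            for c in d.calls
            if c.condition is not None
        }
        if label.canonical not in observed:
            raise ValueError(f"unknown condition {label.canonical!r}")
    return label


def _resolve_comparison(
    comparison: Union[str, Comparison], corpus: Corpus
) -> Comparison:
    comp = parse_comparison(comparison)
    members = {c.canonical for c in comp}
    if members <= KNOWN_CONDITIONS:
        return comp
    observed: set[tuple[str, str]] = {
        comparison_key(c.comparison)
        for d in corpus.datasets
        for c in d.calls
        if c.comparison is not None
    }
    key = comparison_key(comp)
    if key not in observed and key[::-1] not in observed:
        raise ValueError(f"unknown comparison {key[0]}_vs_{key[1]!s}")
    return comp


def _status_votes(
    corpus: Corpus, condition: ConditionLabel
) -> dict[str, tuple[set[str], set[str]]]:
    """Per symbol: (datasets voting expressed, datasets voting not-detected)."""
    votes: dict[str, tuple[set[str], set[str]]] = {}
    for d in corpus.datasets:
        for c in d.calls:
            if c.condition is None or c.condition.canonical != condition.canonical:
                continue
            exp, nd = votes.setdefault(c.symbol, (set(), set()))
            (exp if c.call is Call.EXPRESSED else nd).add(d.dataset_id)
    return votes


def _pattern_votes(
    corpus: Corpus, comparison: Comparison
) -> dict[str, tuple[set[str], set[str]]]:
    """Per symbol: (datasets voting up, datasets voting down), after orienting
    reversed-pair datasets to the requested comparison."""
    fwd = comparison_key(comparison)
    rev = fwd[::-1]
    votes: dict[str, tuple[set[str], set[str]]] = {}
    for d in corpus.datasets:
        for c in d.calls:
            if c.comparison is None:
                continue
            key = comparison_key(c.comparison)
            if key == fwd:
                call = c.call
            elif key == rev:
                call = c.call.opposite
            else:
                continue
            up, down = votes.setdefault(c.symbol, (set(), set()))
            (up if call is Call.UP else down).add(d.dataset_id)
    return votes


def score_status(
    symbol: str, condition: Union[str, ConditionLabel], corpus: Corpus
) -> StatusScore:
    """Score a gene's expression status in one condition.

    Each dataset contributes at most one vote per status; a gene absent from
    the corpus scores (0, 0) rather than erroring.
    """
    label = _resolve_condition(condition, corpus)
    symbol = normalize_symbol(symbol)
    exp, nd = _status_votes(corpus, label).get(symbol, (set(), set()))
    return StatusScore(
        symbol=symbol, condition=label, n_expressed=len(exp), n_not_detected=len(nd)
    )


def score_pattern(
    symbol: str, comparison: Union[str, Comparison], corpus: Corpus
) -> PatternScore:
    """Score a gene's expression pattern for one ordered condition pair."""
    comp = _resolve_comparison(comparison, corpus)
    symbol = normalize_symbol(symbol)
    up, down = _pattern_votes(corpus, comp).get(symbol, (set(), set()))
    return PatternScore(symbol=symbol, comparison=comp, n_up=len(up), n_down=len(down))


def cumulative_scores(status: StatusScore, pattern: PatternScore) -> GeneScoreCard:
    """Combine status and pattern scores into one card.

    The status condition must be the first member of the pattern's comparison
    (the condition the directions are expressed relative to).
    """
    if status.symbol != pattern.symbol:
        raise ValueError(
            f"symbol mismatch: status is for {status.symbol!r}, "
            f"pattern for {pattern.symbol!r}"
        )
    if status.condition.canonical != pattern.comparison[0].canonical:
        raise ValueError(
            f"status condition {status.condition.canonical!r} is not the first "
            f"member of comparison {comparison_key(pattern.comparison)}"
        )
    return GeneScoreCard(symbol=status.symbol, status=status, pattern=pattern)


def card_sort_key(card: GeneScoreCard) -> tuple:
    """Ranking: cumulative desc, pattern score desc, then symbol lexicographic."""
    return (-card.cumulative_upex, -card.pattern.up_score, card.symbol)


def score_all(
    corpus: Corpus, comparison: Union[str, Comparison]
) -> list[GeneScoreCard]:
    """Score every symbol in the corpus against one comparison.

    The status dimension is evaluated in the comparison's first condition.
    Output is deterministically ordered by :func:`card_sort_key`.
    """
    comp = _resolve_comparison(comparison, corpus)
    condition = comp[0]
    status_votes = _status_votes(corpus, condition)
    pattern_votes = _pattern_votes(corpus, comp)
    cards = []
    for symbol in sorted(corpus.symbols):
        exp, nd = status_votes.get(symbol, (set(), set()))
        up, down = pattern_votes.get(symbol, (set(), set()))
        cards.append(
            GeneScoreCard(
                symbol=symbol,
                status=StatusScore(
                    symbol=symbol,
                    condition=condition,
                    n_expressed=len(exp),
                    n_not_detected=len(nd),
                ),
                pattern=PatternScore(
                    symbol=symbol, comparison=comp, n_up=len(up), n_down=len(down)
                ),
            )
        )
    cards.sort(key=card_sort_key)
    return cards
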