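"""Ingestion, validation and persistence of curated gene-list datasets.

A *dataset* is one curated gene list from a single study condition: a set of
per-gene assertions ("calls") that a gene was expressed, not detected,
upregulated or downregulated. Datasets carry study metadata and are bundled
into a :class:`Corpus`, the unit consumed by the scoring engine.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Minimum list length used during curation; shorter lists are accepted with
#: a warning rather than rejected.
MIN_GENES = 5

# sha256 of the packaged consensus tables (guards against silent edits)
_FIXTURE_CHECKSUMS = {
    "tables_1_3_upex.tsv": "2617ca46e015df25aea8bf729d5ecbe611a3dee9598621a4ba1f0f6c021b909e",
    "table_4_downnd.tsv": "5666ac74e5dfa4203bca551edd844b01db783d564589e22d2ebb7db8e4134676",
}


class GenelistError(ValueError):
    """Malformed gene-list input; carries per-row diagnostics."""

    def __init__(self, message: str, row_errors: Optional[Sequence[tuple[int, str]]] = None):
        self.row_errors = list(row_errors or [])
        if self.row_errors:
            detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.row_errors)
            message = f"{message}: {detail}"
        super().__init__(message)


class ContradictionError(GenelistError):
    """A single dataset asserts opposing calls for the same gene."""


class Call(str, enum.Enum):
    """One curated assertion about a gene in a dataset."""

    EXPRESSED = "expressed"
    NOT_DETECTED = "not_detected"
    UP = "up"
    DOWN = "down"

    @property
    def is_status(self) -> bool:
        return self in (Call.EXPRESSED, Call.NOT_DETECTED)

    @property
    def is_pattern(self) -> bool:
        return self in (Call.UP, Call.DOWN)

    @property
    def opposite(self) -> "Call":
        return _OPPOSITE[self]


_OPPOSITE = {
    Call.EXPRESSED: Call.NOT_DETECTED,
    Call.NOT_DETECTED: Call.EXPRESSED,
    Call.UP: Call.DOWN,
    Call.DOWN: Call.UP,
}


class Strategy(str, enum.Enum):
    MICROARRAY = "microarray"
    PROTEOMICS = "proteomics"
    QRT_PCR = "qrt_pcr"
    OTHER = "other"


class Cohort(str, enum.Enum):
    HEALTHY = "healthy"
    DISORDER = "disorder"
    STIMULATED = "stimulated"
    IVF_FAILURE = "ivf_failure"


#: Canonical condition tokens. Anything else canonicalizes to ``other(<raw>)``.
KNOWN_CONDITIONS = frozenset(
    {"pre_receptive", "receptive", "proliferative", "secretory"}
)

#: Default raw-label -> canonical condition map (lower-cased keys).
#: User-supplied maps extend/override these entries.
DEFAULT_CONDITION_MAP: dict[str, str] = {
    "receptive": "receptive",
    "receptive phase": "receptive",
    "mid-secretory": "receptive",
    "mid secretory": "receptive",
    "mid_secretory": "receptive",
    "lh+7": "receptive",
    "lh+8": "receptive",
    "window of implantation": "receptive",
    "pre-receptive": "pre_receptive",
    "pre_receptive": "pre_receptive",
    "prereceptive": "pre_receptive",
    "pre-receptive phase": "pre_receptive",
    "early secretory": "pre_receptive",
    "early-secretory": "pre_receptive",
    "early_secretory": "pre_receptive",
    "lh+2": "pre_receptive",
    "proliferative": "proliferative",
    "mid-proliferative": "proliferative",
    "mid proliferative": "proliferative",
    "late proliferative": "proliferative",
    "secretory": "secretory",
}


@dataclass(frozen=True)
class ConditionLabel:
    """A curated condition label and its deterministic canonical form."""

    raw_label: str
    canonical: str

    @classmethod
    def from_raw(
        cls, raw: str, condition_map: Optional[Mapping[str, str]] = None
    ) -> "ConditionLabel":
        """Canonicalize ``raw`` via the condition map.

        Unmapped labels are tagged ``other(<raw>)`` rather than dropped.
        """
        table = dict(DEFAULT_CONDITION_MAP)
        if condition_map:
            table.update({k.strip().lower(): v for k, v in condition_map.items()})
        key = raw.strip().lower()
        canonical = table.get(key)
        if canonical is None:
            canonical = key if key in KNOWN_CONDITIONS else f"other({raw.strip()})"
        return cls(raw_label=raw, canonical=canonical)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical


Comparison = tuple[ConditionLabel, ConditionLabel]


def parse_comparison(
    spec: Union[str, Comparison, Sequence],
    condition_map: Optional[Mapping[str, str]] = None,
) -> Comparison:
    """Parse an ordered condition pair.

    Accepts a ``"<first>_vs_<second>"`` string (e.g.
    ``"receptive_vs_pre_receptive"``) or a pair of labels/strings. "Up" always
    means higher in the first-named condition.
    """
    if isinstance(spec, str):
        parts = spec.split("_vs_")
        if len(parts) != 2:
            raise ValueError(f"cannot parse comparison {spec!r}: expected '<a>_vs_<b>'")
        first, second = parts
    else:
        first, second = spec
    pair = tuple(
        c if isinstance(c, ConditionLabel) else ConditionLabel.from_raw(c, condition_map)
        for c in (first, second)
    )
    if pair[0].canonical == pair[1].canonical:
        raise ValueError(f"comparison members must differ, got {pair[0].canonical!r} twice")
    return pair  # type: ignore[return-value]


def comparison_key(comparison: Comparison) -> tuple[str, str]:
    return (comparison[0].canonical, comparison[1].canonical)


@dataclass(frozen=True)
class GeneCall:
    """One (gene, call) assertion inside a dataset.

    Status calls (expressed / not detected) carry exactly one condition;
    pattern calls (up / down) carry exactly one ordered condition pair.
    """

    symbol: str
    call: Call
    source_dataset: str
    condition: Optional[ConditionLabel] = None
    comparison: Optional[Comparison] = None

    def __post_init__(self) -> None:
        if self.call.is_status:
            if self.condition is None or self.comparison is not None:
                raise ValueError(
                    f"status call {self.call.value!r} for {self.symbol!r} must carry "
                    "exactly one condition and no comparison"
                )
        else:
            if self.comparison is None or self.condition is not None:
                raise ValueError(
                    f"pattern call {self.call.value!r} for {self.symbol!r} must carry "
                    "exactly one ordered condition pair and no condition"
                )

    def dedup_key(self):
        cond = self.condition.canonical if self.condition else None
        comp = comparison_key(self.comparison) if self.comparison else None
        return (self.symbol, self.call, cond, comp)

    def contradiction_key(self):
        """Key shared by a call and its opposite within one dataset."""
        cond = self.condition.canonical if self.condition else None
        comp = comparison_key(self.comparison) if self.comparison else None
        kind = "status" if self.call.is_status else "pattern"
        return (self.symbol, kind, cond, comp)


@dataclass
class StudyMetadata:
    """Curation metadata for one study/dataset."""

    study_id: str
    ethnicity: str = ""
    treatment: str = "none"
    sample_size: Optional[int] = None
    strategy: Strategy = Strategy.OTHER
    platform: str = ""
    n_hybridizations: int = 0
    validation: str = ""
    stats_method: str = ""
    cohort: Cohort = Cohort.HEALTHY

    def __post_init__(self) -> None:
        self.strategy = Strategy(self.strategy)
        self.cohort = Cohort(self.cohort)
        if self.sample_size is not None and self.sample_size < 1:
            raise ValueError(f"sample_size must be >= 1, got {self.sample_size}")
        if self.n_hybridizations < 0:
            raise ValueError(f"n_hybridizations must be >= 0, got {self.n_hybridizations}")


@dataclass
class DatasetRecord:
    """One curated gene list with its metadata and condition: the scoring unit."""

    dataset_id: str
    metadata: StudyMetadata
    condition: ConditionLabel
    calls: list[GeneCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.source_dataset != self.dataset_id:
                raise ValueError(
                    f"call for {c.symbol!r} sourced from {c.source_dataset!r}, "
                    f"expected {self.dataset_id!r}"
                )
        self._check_contradictions()

    def _check_contradictions(self) -> None:
        seen: dict[tuple, Call] = {}
        for c in self.calls:
            key = c.contradiction_key()
            prev = seen.get(key)
            if prev is not None and prev is not c.call:
                raise ContradictionError(
                    f"dataset {self.dataset_id!r} asserts both {prev.value!r} and "
                    f"{c.call.value!r} for gene {c.symbol!r}"
                )
            seen[key] = c.call

    @property
    def symbols(self) -> set[str]:
        return {c.symbol for c in self.calls}


@dataclass
class AliasMap:
    """Alias -> canonical symbol lookup (a function; canonicals are fixed points)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for alias, target in self.mapping.items():
            a = normalize_symbol(alias)
            t = normalize_symbol(target)
            if a in norm and norm[a] != t:
                raise ValueError(f"alias {a!r} maps to both {norm[a]!r} and {t!r}")
            norm[a] = t
        # canonical symbols map to themselves
        for t in list(norm.values()):
            if t in norm and norm[t] != t:
                raise ValueError(f"canonical symbol {t!r} remaps to {norm[t]!r}")
            norm[t] = t
        self.mapping = norm

    def resolve(self, symbol: str) -> str:
        s = normalize_symbol(symbol)
        return self.mapping.get(s, s)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class Corpus:
    """A collection of datasets plus the alias map used to harmonize them."""

    datasets: list[DatasetRecord] = field(default_factory=list)
    alias_map: AliasMap = field(default_factory=AliasMap)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate dataset ids in corpus: {dupes}")

    @property
    def symbols(self) -> set[str]:
        out: set[str] = set()
        for d in self.datasets:
            out |= d.symbols
        return out

    def digest(self) -> str:
        """Stable provenance hash of the corpus content."""
        blob = json.dumps(corpus_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip whitespace — microarray annotations mix cases."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

_CALL_ALIASES = {
    "expressed": Call.EXPRESSED,
    "present": Call.EXPRESSED,
    "not_detected": Call.NOT_DETECTED,
    "not-detected": Call.NOT_DETECTED,
    "absent": Call.NOT_DETECTED,
    "up": Call.UP,
    "upregulated": Call.UP,
    "down": Call.DOWN,
    "downregulated": Call.DOWN,
}


def _sniff_delimiter(first_line: str) -> str:
    # TSV default; comma auto-detected when no tab present
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return "\t"


def read_genelist(
    path: Union[str, Path],
    metadata: StudyMetadata,
    condition: Union[str, ConditionLabel, None] = None,
    comparison: Union[str, Comparison, None] = None,
    condition_map: Optional[Mapping[str, str]] = None,
    dataset_id: Optional[str] = None,
) -> DatasetRecord:
    """Read one delimited gene list into a validated :class:`DatasetRecord`.

    The file must have a header row with at least ``symbol`` and ``call``
    columns; optional ``condition`` and ``comparison`` columns override the
    dataset-level defaults per row. Duplicate (symbol, call) rows collapse to
    one call; lists with fewer than ``MIN_GENES`` genes trigger a warning;
    contradictory calls reject the whole dataset.
    """
    path = Path(path)
    dataset_id = dataset_id or path.stem
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise GenelistError(f"{path}: no calls (empty file)")

    first_line = text.splitlines()[0]
    delim = _sniff_delimiter(first_line)
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    fields = [f.strip().lower() for f in reader.fieldnames or []]
    reader.fieldnames = fields
    for required in ("symbol", "call"):
        if required not in fields:
            raise GenelistError(f"{path}: missing required column {required!r}")

    default_condition = (
        condition
        if isinstance(condition, ConditionLabel)
        else (ConditionLabel.from_raw(condition, condition_map) if condition else None)
    )
    default_comparison = parse_comparison(comparison, condition_map) if comparison else None

    calls: list[GeneCall] = []
    row_errors: list[tuple[int, str]] = []
    for line_no, row in enumerate(reader, start=2):
        symbol = normalize_symbol(row.get("symbol") or "")
        raw_call = (row.get("call") or "").strip().lower()
        if not symbol:
            row_errors.append((line_no, "missing gene symbol"))
            continue
        call = _CALL_ALIASES.get(raw_call)
        if call is None:
            row_errors.append((line_no, f"unrecognized call {raw_call!r}"))
            continue
        try:
            if call.is_status:
                cond_raw = (row.get("condition") or "").strip()
                cond = (
                    ConditionLabel.from_raw(cond_raw, condition_map)
                    if cond_raw
                    else default_condition
                )
                if cond is None:
                    row_errors.append((line_no, "status call without a condition"))
                    continue
                calls.append(
                    GeneCall(symbol=symbol, call=call, condition=cond, source_dataset=dataset_id)
                )
            else:
                comp_raw = (row.get("comparison") or "").strip()
                comp = (
                    parse_comparison(comp_raw, condition_map) if comp_raw else default_comparison
                )
                if comp is None:
                    row_errors.append((line_no, "pattern call without a comparison"))
                    continue
                calls.append(
                    GeneCall(symbol=symbol, call=call, comparison=comp, source_dataset=dataset_id)
                )
        except ValueError as exc:
            row_errors.append((line_no, str(exc)))

    if row_errors:
        raise GenelistError(f"{path}: malformed rows", row_errors)
    if not calls:
        raise GenelistError(f"{path}: no calls")

    calls = _dedup(calls)
    dataset_condition = default_condition
    if dataset_condition is None:
        dataset_condition = next((c.condition for c in calls if c.condition), None)
    if dataset_condition is None and default_comparison is not None:
        dataset_condition = default_comparison[0]
    if dataset_condition is None:
        dataset_condition = next(c.comparison[0] for c in calls if c.comparison)
    record = DatasetRecord(
        dataset_id=dataset_id, metadata=metadata, condition=dataset_condition, calls=calls
    )
    if len(record.symbols) < MIN_GENES:
        warnings.warn(
            f"dataset {dataset_id!r}: below {MIN_GENES}-gene curation threshold "
            f"({len(record.symbols)} genes)",
            UserWarning,
            stacklevel=2,
        )
    return record


def _dedup(calls: Iterable[GeneCall]) -> list[GeneCall]:
    seen: set = set()
    out: list[GeneCall] = []
    for c in calls:
        k = c.dedup_key()
        if k not in seen:
            seen.add(k)
            out.append(c)
    return out


def _drop_collisions(calls: list[GeneCall], context: str) -> list[GeneCall]:
    """Drop both sides of any post-merge contradiction, logging each event."""
    by_key: dict[tuple, set[Call]] = {}
    for c in calls:
        by_key.setdefault(c.contradiction_key(), set()).add(c.call)
    bad = {k for k, v in by_key.items() if len(v) > 1}
    if bad:
        for k in sorted(bad, key=str):
            logger.warning(
                "%s: contradictory calls for gene %s after merge; dropping both sides",
                context,
                k[0],
            )
    return [c for c in calls if c.contradiction_key() not in bad]


def harmonize_symbols(dataset: DatasetRecord, aliases: AliasMap) -> DatasetRecord:
    """Replace every symbol by its canonical form; idempotent.

    If harmonization makes two calls collide into a contradiction (one alias
    said expressed, another said not detected), both calls are dropped and the
    event logged. Unknown symbols pass through case-normalized.
    """
    new_calls = [replace(c, symbol=aliases.resolve(c.symbol)) for c in dataset.calls]
    new_calls = _dedup(new_calls)
    new_calls = _drop_collisions(new_calls, f"dataset {dataset.dataset_id}")
    return DatasetRecord(
        dataset_id=dataset.dataset_id,
        metadata=dataset.metadata,
        condition=dataset.condition,
        calls=new_calls,
    )


def harmonize_corpus(corpus: Corpus) -> Corpus:
    return Corpus(
        datasets=[harmonize_symbols(d, corpus.alias_map) for d in corpus.datasets],
        alias_map=corpus.alias_map,
        provenance=corpus.provenance,
    )


def collapse_by_study(corpus: Corpus) -> Corpus:
    """Merge same-study datasets by call union (publication-level scoring).

    Datasets sharing ``metadata.study_id`` are merged into one record whose
    calls are the union of the members' calls; contradictions arising from
    the union are dropped pairwise and logged.
    """
    groups: dict[str, list[DatasetRecord]] = {}
    for d in corpus.datasets:
        groups.setdefault(d.metadata.study_id, []).append(d)
    merged: list[DatasetRecord] = []
    for study_id, members in groups.items():
        if len(members) == 1 and members[0].dataset_id == study_id:
            merged.append(members[0])
            continue
        calls = [
            replace(c, source_dataset=study_id) for d in members for c in d.calls
        ]
        calls = _dedup(calls)
        calls = _drop_collisions(calls, f"study {study_id}")
        merged.append(
            DatasetRecord(
                dataset_id=study_id,
                metadata=members[0].metadata,
                condition=members[0].condition,
                calls=calls,
            )
        )
    return Corpus(datasets=merged, alias_map=corpus.alias_map, provenance=corpus.provenance)


# ---------------------------------------------------------------------------
# persistence (schema-versioned JSON)
# ---------------------------------------------------------------------------


def _condition_to_dict(c: ConditionLabel) -> dict:
    return {"raw_label": c.raw_label, "canonical": c.canonical}


def _condition_from_dict(d: dict) -> ConditionLabel:
    return ConditionLabel(raw_label=d["raw_label"], canonical=d["canonical"])


def _call_to_dict(c: GeneCall) -> dict:
    out: dict = {"symbol": c.symbol, "call": c.call.value}
    if c.condition is not None:
        out["condition"] = _condition_to_dict(c.condition)
    if c.comparison is not None:
        out["comparison"] = [_condition_to_dict(x) for x in c.comparison]
    return out


def _call_from_dict(d: dict, source_dataset: str) -> GeneCall:
    return GeneCall(
        symbol=d["symbol"],
        call=Call(d["call"]),
        source_dataset=source_dataset,
        condition=_condition_from_dict(d["condition"]) if "condition" in d else None,
        comparison=(
            tuple(_condition_from_dict(x) for x in d["comparison"])
            if "comparison" in d
            else None
        ),
    )


def corpus_to_dict(corpus: Corpus) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "provenance": corpus.provenance,
        "alias_map": dict(sorted(corpus.alias_map.mapping.items())),
        "datasets": [
            {
                "dataset_id": d.dataset_id,
                "metadata": {
                    "study_id": d.metadata.study_id,
                    "ethnicity": d.metadata.ethnicity,
                    "treatment": d.metadata.treatment,
                    "sample_size": d.metadata.sample_size,
                    "strategy": d.metadata.strategy.value,
                    "platform": d.metadata.platform,
                    "n_hybridizations": d.metadata.n_hybridizations,
                    "validation": d.metadata.validation,
                    "stats_method": d.metadata.stats_method,
                    "cohort": d.metadata.cohort.value,
                },
                "condition": _condition_to_dict(d.condition),
                "calls": [_call_to_dict(c) for c in d.calls],
            }
            for d in corpus.datasets
        ],
    }


def corpus_from_dict(doc: dict) -> Corpus:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported corpus schema version {version!r}")
    datasets = []
    for dd in doc["datasets"]:
        md = StudyMetadata(**dd["metadata"])
        datasets.append(
            DatasetRecord(
                dataset_id=dd["dataset_id"],
                metadata=md,
                condition=_condition_from_dict(dd["condition"]),
                calls=[_call_from_dict(cd, dd["dataset_id"]) for cd in dd["calls"]],
            )
        )
    return Corpus(
        datasets=datasets,
        alias_map=AliasMap(dict(doc.get("alias_map", {}))),
        provenance=doc.get("provenance", ""),
    )


def write_corpus(corpus: Corpus, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(corpus_to_dict(corpus), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_corpus(path: Union[str, Path]) -> Corpus:
    return corpus_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# packaged consensus tables
# ---------------------------------------------------------------------------


def _read_fixture(name: str) -> list[dict]:
    ref = resources.files("ragscore.data") / name
    body = ref.read_text(encoding="utf-8")
    digest = hashlib.sha256(body.encode()).hexdigest()
    expected = _FIXTURE_CHECKSUMS[name]
    if digest != expected:
        raise ValueError(
            f"fixture {name!r} checksum mismatch: {digest} != {expected}"
        )
    return list(csv.DictReader(body.splitlines(), delimiter="\t"))


def load_fixture_tables():
    """Load the packaged published consensus gene tables as a RAGResult.

    Returns the 151-gene Up-Ex and 28-gene Down-Nd reference lists with their
    pattern, status and cumulative scores, for regression testing.
    """
    from .rags import RAGEntry, RAGParams, RAGResult  # local import avoids a cycle

    def entries(name: str) -> list:
        return [
            RAGEntry(
                symbol=r["symbol"],
                name=r["name"],
                pattern_score=int(r["pattern_score"]),
                status_score=int(r["status_score"]),
                cumulative=int(r["cumulative_score"]),
            )
            for r in _read_fixture(name)
        ]

    digest = hashlib.sha256(
        "".join(_FIXTURE_CHECKSUMS[k] for k in sorted(_FIXTURE_CHECKSUMS)).encode()
    ).hexdigest()
    return RAGResult(
        up_ex=entries("tables_1_3_upex.tsv"),
        down_nd=entries("table_4_downnd.tsv"),
        params=RAGParams(),
        corpus_digest=digest,
    )
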