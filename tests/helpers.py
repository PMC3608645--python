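"""Shared builders, the independent brute-force oracle, and hypothesis strategies."""

from __future__ import annotations

from hypothesis import strategies as st

from ragscore import (
    AliasMap,
    Call,
    Cohort,
    ConditionLabel,
    Corpus,
    DatasetRecord,
    GeneCall,
    StudyMetadata,
)

RECEPTIVE = ConditionLabel.from_raw("receptive")
PRE_RECEPTIVE = ConditionLabel.from_raw("pre-receptive")
FWD = (RECEPTIVE, PRE_RECEPTIVE)
REV = (PRE_RECEPTIVE, RECEPTIVE)
COMPARISON = "receptive_vs_pre_receptive"


def make_dataset(dataset_id, calls, cohort=Cohort.HEALTHY, study_id=None):
    """Build a dataset from (symbol, call[, orientation]) tuples.

    ``call`` is a Call or its string value. Status calls attach to the
    receptive condition; pattern calls attach to the forward comparison
    unless orientation "rev" is given.
    """
    gene_calls = []
    for item in calls:
        symbol, call = item[0], Call(item[1])
        orientation = item[2] if len(item) > 2 else "fwd"
        if call.is_status:
            gene_calls.append(
                GeneCall(symbol=symbol, call=call, condition=RECEPTIVE,
                         source_dataset=dataset_id)
            )
        else:
            comp = FWD if orientation == "fwd" else REV
            gene_calls.append(
                GeneCall(symbol=symbol, call=call, comparison=comp,
                         source_dataset=dataset_id)
            )
    return DatasetRecord(
        dataset_id=dataset_id,
        metadata=StudyMetadata(study_id=study_id or dataset_id, cohort=cohort),
        condition=RECEPTIVE,
        calls=gene_calls,
    )


def make_corpus(*datasets):
    return Corpus(datasets=list(datasets), alias_map=AliasMap())


def vote_corpus(symbol="GENE1", n_expressed=0, n_up=0, n_not_detected=0, n_down=0,
                extra_symbols=()):
    """One gene receiving the requested number of single-vote datasets.

    Status and pattern votes are packed into shared datasets where possible
    (a dataset may carry one status and one pattern call for the gene).
    """
    n_datasets = max(n_expressed + n_not_detected, n_up + n_down, 1)
    datasets = []
    for i in range(n_datasets):
        calls = []
        if i < n_expressed:
            calls.append((symbol, Call.EXPRESSED))
        elif i < n_expressed + n_not_detected:
            calls.append((symbol, Call.NOT_DETECTED))
        if i < n_up:
            calls.append((symbol, Call.UP))
        elif i < n_up + n_down:
            calls.append((symbol, Call.DOWN))
        for s in extra_symbols:
            calls.append((s, Call.EXPRESSED))
        datasets.append(make_dataset(f"DS{i:02d}", calls))
    return make_corpus(*datasets)


# ---------------------------------------------------------------------------
# independent oracle: direct enumeration over the raw call lists
# ---------------------------------------------------------------------------


def oracle_counts(corpus, symbol, condition_canonical, comparison_canonicals):
    """Brute-force tally of distinct datasets backing each call for a gene.

    Deliberately re-derives everything from the raw structures: walks every
    dataset, collects ids per call kind, flips pattern calls curated against
    the reversed pair. Returns (n_expressed, n_not_detected, n_up, n_down).
    """
    exp, nd, up, down = set(), set(), set(), set()
    rev = (comparison_canonicals[1], comparison_canonicals[0])
    for ds in corpus.datasets:
        for call in ds.calls:
            if call.symbol != symbol:
                continue
            if call.condition is not None:
                if call.condition.canonical != condition_canonical:
                    continue
                if call.call is Call.EXPRESSED:
                    exp.add(ds.dataset_id)
                else:
                    nd.add(ds.dataset_id)
            else:
                pair = (call.comparison[0].canonical, call.comparison[1].canonical)
                if pair == tuple(comparison_canonicals):
                    direction = call.call
                elif pair == rev:
                    direction = Call.UP if call.call is Call.DOWN else Call.DOWN
                else:
                    continue
                if direction is Call.UP:
                    up.add(ds.dataset_id)
                else:
                    down.add(ds.dataset_id)
    return len(exp), len(nd), len(up), len(down)


# ---------------------------------------------------------------------------
# hypothesis strategies
# ---------------------------------------------------------------------------

_SYMBOLS = [f"GN{i:02d}" for i in range(20)]


@st.composite
def random_corpora(draw, max_genes=20, max_datasets=10):
    """Random contradiction-free-within-dataset corpora.

    Each dataset assigns at most one status and one pattern call per gene,
    so within-dataset contradictions (rejected at ingestion) cannot occur;
    cross-dataset disagreement is free to occur.
    """
    n_genes = draw(st.integers(1, max_genes))
    n_datasets = draw(st.integers(1, max_datasets))
    genes = _SYMBOLS[:n_genes]
    datasets = []
    for d in range(n_datasets):
        calls = []
        for g in genes:
            status = draw(st.sampled_from([None, Call.EXPRESSED, Call.NOT_DETECTED]))
            if status is not None:
                calls.append((g, status))
            pattern = draw(st.sampled_from([None, Call.UP, Call.DOWN]))
            if pattern is not None:
                orientation = draw(st.sampled_from(["fwd", "rev"]))
                calls.append((g, pattern, orientation))
        datasets.append(make_dataset(f"DS{d:02d}", calls))
    return make_corpus(*datasets)
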