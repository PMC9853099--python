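"""High-level map / all-vs-all overlap drivers over index + chaining."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Sequence

from fuzzyseed.chaining import (
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_ANCHORS,
    DEFAULT_MIN_CHAIN_SCORE,
    chain_anchors,
    chains_to_records,
    collect_anchors,
)
from fuzzyseed.core_hashing import SimHashConfig
from fuzzyseed.formats import PafRecord, SeqRecord
from fuzzyseed.indexing import DEFAULT_MAX_OCC, SeedIndex, build_index, filter_frequent
from fuzzyseed.seeding import SeedingParams


@dataclass(frozen=True)
class ChainingOptions:
    max_gap: int = DEFAULT_MAX_GAP
    min_chain_score: int = DEFAULT_MIN_CHAIN_SCORE
    min_anchors: int = DEFAULT_MIN_ANCHORS


def map_queries(
    index: SeedIndex,
    queries: Iterable[SeqRecord],
    options: ChainingOptions = ChainingOptions(),
    exclude_self: bool = False,
) -> Iterator[PafRecord]:
    """Map each query against the index, yielding PAF records per chain."""
    for query in queries:
        anchors = collect_anchors(
            index, query, index.params, index.cfg,
            query_id=query.name, exclude_self=exclude_self,
        )
        chains = chain_anchors(
            anchors,
            max_gap=options.max_gap,
            min_chain_score=options.min_chain_score,
            min_anchors=options.min_anchors,
        )
        yield from chains_to_records(chains, query.name, len(query.seq), index.target_lengths)


def overlap_reads(
    reads: Sequence[SeqRecord],
    params: SeedingParams,
    cfg: SimHashConfig,
    options: ChainingOptions = ChainingOptions(),
    max_occ: int = DEFAULT_MAX_OCC,
) -> List[PafRecord]:
    """All-vs-all read overlapping: target set = query set, self hits suppressed."""
    index = filter_frequent(build_index(reads, params, cfg), max_occ)
    return list(map_queries(index, reads, options, exclude_self=True))
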