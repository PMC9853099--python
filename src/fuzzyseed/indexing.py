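"""Hash-table index over target seeds and single-lookup fuzzy queries.

Keys of the table are seed hash values; each key maps to the list of
coordinate records of target seeds carrying that value.  Because similar
seeds receive the same fuzzy hash, one lookup of a query seed's hash
returns both its exact and its approximate matches.  The index stores no
sequence text, only coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List

from fuzzyseed.core_hashing import SimHashConfig
from fuzzyseed.formats import SeqRecord
from fuzzyseed.seeding import SeedingParams, seed_stream

logger = logging.getLogger(__name__)

DEFAULT_MAX_OCC = 1000

INDEX_FORMAT_VERSION = 1


class NoTargetsError(ValueError):
    """No target sequences supplied to the indexing step."""


@dataclass(frozen=True)
class IndexRecord:
    """Minimal metadata locating one seed in a target sequence."""

    seq_id: str
    start: int
    span: int
    strand: str

    def __post_init__(self) -> None:
        if self.span < 1 or self.start < 0:
            raise ValueError("IndexRecord requires span >= 1 and start >= 0")


@dataclass
class SeedIndex:
    table: Dict[int, List[IndexRecord]]
    params: SeedingParams
    cfg: SimHashConfig
    target_lengths: Dict[str, int]
    dropped_keys: int = 0

    @property
    def n_keys(self) -> int:
        return len(self.table)

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.table.values())


def build_index(
    targets: Iterable[SeqRecord], params: SeedingParams, cfg: SimHashConfig
) -> SeedIndex:
    """Insert every seed of every target under its hash value.

    Record lists under one key are sorted by (seq_id, start) so downstream
    anchor collection and chaining are deterministic for fixed inputs and
    hash seed.  Raises :class:`NoTargetsError` on an empty input.
    """
    table: Dict[int, List[IndexRecord]] = {}
    target_lengths: Dict[str, int] = {}
    any_target = False
    for rec in targets:
        any_target = True
        target_lengths[rec.name] = len(rec.seq)
        for seed in seed_stream(rec.seq, params, cfg, seq_id=rec.name):
            table.setdefault(seed.hash, []).append(
                IndexRecord(seed.seq_id, seed.start, seed.span, seed.strand)
            )
    if not any_target:
        raise NoTargetsError("no targets")
    for records in table.values():
        records.sort(key=lambda r: (r.seq_id, r.start))
    index = SeedIndex(table=table, params=params, cfg=cfg, target_lengths=target_lengths)
    logger.info(
        "indexed %d sequences: %d keys, %d seed records",
        len(target_lengths), index.n_keys, index.n_records,
    )
    return index


def filter_frequent(index: SeedIndex, max_occ: int = DEFAULT_MAX_OCC) -> SeedIndex:
    """Drop keys whose record list exceeds ``max_occ`` (repeat masking).

    Returns a new index; the count of dropped keys is logged and recorded
    on the result.  Never increases any list length and never adds keys.
    """
    if max_occ < 1:
        raise ValueError("max_occ must be >= 1")
    kept = {h: recs for h, recs in index.table.items() if len(recs) <= max_occ}
    dropped = index.n_keys - len(kept)
    if dropped:
        logger.info("frequency filter dropped %d of %d keys (max_occ=%d)",
                    dropped, index.n_keys, max_occ)
    return SeedIndex(
        table=kept,
        params=index.params,
        cfg=index.cfg,
        target_lengths=dict(index.target_lengths),
        dropped_keys=index.dropped_keys + dropped,
    )


def query_index(index: SeedIndex, hash_value: int) -> List[IndexRecord]:
    """All target records sharing ``hash_value`` -- one lookup, no scanning.

    This single lookup is the fuzzy seed match: similar seeds were given the
    same hash at build time, so their records sit in the same bucket.
    An absent key returns an empty list.
    """
    return index.table.get(hash_value, [])


def save_index(index: SeedIndex, path: str) -> None:
    """Serialize to a versioned JSON container (params and config embedded)."""
    payload = {
        "format_version": INDEX_FORMAT_VERSION,
        "params": dataclasses.asdict(index.params),
        "cfg": dataclasses.asdict(index.cfg),
        "target_lengths": index.target_lengths,
        "dropped_keys": index.dropped_keys,
        "table": {
            str(h): [[r.seq_id, r.start, r.span, r.strand] for r in recs]
            for h, recs in sorted(index.table.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, separators=(",", ":"), sort_keys=True)


def load_index(path: str) -> SeedIndex:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format: {payload.get('format_version')}")
    return SeedIndex(
        table={
            int(h): [IndexRecord(*rec) for rec in recs]
            for h, recs in payload["table"].items()
        },
        params=SeedingParams(**payload["params"]),
        cfg=SimHashConfig(**payload["cfg"]),
        target_lengths={k: int(v) for k, v in payload["target_lengths"].items()},
        dropped_keys=int(payload.get("dropped_keys", 0)),
    )
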