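"""Co-linear chaining of fuzzy seed matches into overlap/mapping records.

Each query-seed/target-record pair with equal hash is an :class:`Anchor`.
Anchors on the same target and strand pairing are chained by dynamic
programming that maximizes ``sum(anchor spans) - sum(gap costs)`` where the
gap cost between consecutive anchors is the diagonal drift ``|dq - dt|``
and transitions with ``dq`` or ``dt`` exceeding ``max_gap`` (or
non-monotone) are forbidden.  Chains are extracted best-score-first with
anchor consumption, so each anchor belongs to at most one reported chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from fuzzyseed.core_hashing import SimHashConfig
from fuzzyseed.formats import PafRecord, SeqRecord
from fuzzyseed.indexing import SeedIndex, query_index
from fuzzyseed.seeding import SeedingParams, seed_stream

SAME = "same"
OPPOSITE = "opposite"

DEFAULT_MAX_GAP = 5000
DEFAULT_MIN_CHAIN_SCORE = 40
DEFAULT_MIN_ANCHORS = 3


class IncompatibleIndexError(ValueError):
    """Query run parameters do not match the parameters the index was built with."""


@dataclass(frozen=True)
class Anchor:
    """One fuzzy seed match placed at (query position, target position)."""

    target_id: str
    q_start: int
    t_start: int
    span: int
    strand_pair: str  # SAME or OPPOSITE


@dataclass
class Chain:
    anchors: List[Anchor]
    score: int
    strand_pair: str

    @property
    def q_start(self) -> int:
        return min(a.q_start for a in self.anchors)

    @property
    def q_end(self) -> int:
        return max(a.q_start + a.span for a in self.anchors)

    @property
    def t_start(self) -> int:
        return min(a.t_start for a in self.anchors)

    @property
    def t_end(self) -> int:
        return max(a.t_start + a.span for a in self.anchors)

    @property
    def target_id(self) -> str:
        return self.anchors[0].target_id

    @property
    def matched_bases(self) -> int:
        return sum(a.span for a in self.anchors)


def collect_anchors(
    index: SeedIndex,
    query: Union[str, SeqRecord],
    params: SeedingParams,
    cfg: SimHashConfig,
    query_id: Optional[str] = None,
    exclude_self: bool = False,
) -> List[Anchor]:
    """One anchor per (query seed, same-hash target record) pair.

    In all-vs-all mode (``exclude_self``) matches of a seed against its own
    record (same seq_id, same start) are skipped.  Anchors are sorted by
    (target_id, strand_pair, t_start, q_start).
    """
    if params != index.params or cfg != index.cfg:
        raise IncompatibleIndexError(
            "incompatible index: seeding parameters or hash config differ"
        )
    if hasattr(query, "seq"):
        if query_id is None:
            query_id = query.name
        query = query.seq
    anchors: List[Anchor] = []
    for seed in seed_stream(query, params, cfg, seq_id=query_id or "query"):
        for rec in query_index(index, seed.hash):
            if exclude_self and rec.seq_id == query_id and rec.start == seed.start:
                continue
            pair = SAME if rec.strand == seed.strand else OPPOSITE
            anchors.append(
                Anchor(
                    target_id=rec.seq_id,
                    q_start=seed.start,
                    t_start=rec.start,
                    span=min(seed.span, rec.span),
                    strand_pair=pair,
                )
            )
    anchors.sort(key=lambda a: (a.target_id, a.strand_pair, a.t_start, a.q_start))
    return anchors


def _chain_group(
    anchors: List[Anchor],
    max_gap: int,
    min_chain_score: int,
    min_anchors: int,
) -> List[Chain]:
    """Best-first DP chaining of one (target, strand_pair) anchor group."""
    opposite = anchors[0].strand_pair == OPPOSITE
    # Orient target coordinates so both strand pairings chain on strictly
    # increasing (q, t'); opposite-strand chains decrease in true t.
    q = np.array([a.q_start for a in anchors], dtype=np.int64)
    t = np.array([a.t_start for a in anchors], dtype=np.int64)
    s = np.array([a.span for a in anchors], dtype=np.int64)
    tt = -t if opposite else t
    order = np.lexsort((tt, q))  # primary q, secondary oriented t
    q, tt, s = q[order], tt[order], s[order]
    idx = [anchors[i] for i in order]

    m = len(anchors)
    alive = np.ones(m, dtype=bool)
    chains: List[Chain] = []
    neg_inf = np.int64(np.iinfo(np.int64).min // 4)

    while alive.any():
        dp = np.where(alive, s, neg_inf).astype(np.int64)
        parent = np.full(m, -1, dtype=np.int64)
        for i in range(m):
            if not alive[i]:
                continue
            dq = q[i] - q[:i]
            dt = tt[i] - tt[:i]
            ok = alive[:i] & (dq > 0) & (dt > 0) & (dq <= max_gap) & (dt <= max_gap)
            if not ok.any():
                continue
            cand = dp[:i] - np.abs(dq - dt)
            cand[~ok] = neg_inf
            j = int(cand.argmax())
            if cand[j] > 0:
                dp[i] = s[i] + cand[j]
                parent[i] = j
        best = int(dp.argmax())
        if dp[best] <= neg_inf // 2:
            break
        if dp[best] < min_chain_score:
            break
        members = []
        node = best
        while node != -1:
            members.append(node)
            node = int(parent[node])
        members.reverse()
        for node in members:
            alive[node] = False
        if len(members) >= min_anchors:
            chains.append(
                Chain(
                    anchors=[idx[i] for i in members],
                    score=int(dp[best]),
                    strand_pair=anchors[0].strand_pair,
                )
            )
    return chains


def chain_anchors(
    anchors: Sequence[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    min_chain_score: int = DEFAULT_MIN_CHAIN_SCORE,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
) -> List[Chain]:
    """Chain anchors per (target, strand pairing); empty input gives [].

    Chains scoring below ``min_chain_score`` stop the per-group extraction;
    extracted chains with fewer than ``min_anchors`` members are discarded
    (their anchors stay consumed).  Output is sorted by descending score.
    """
    groups: Dict[Tuple[str, str], List[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.target_id, a.strand_pair), []).append(a)
    chains: List[Chain] = []
    for key in sorted(groups):
        chains.extend(_chain_group(groups[key], max_gap, min_chain_score, min_anchors))
    chains.sort(key=lambda c: (-c.score, c.target_id, c.t_start))
    return chains


def chains_to_records(
    chains: Sequence[Chain],
    query_name: str,
    query_len: int,
    target_lengths: Dict[str, int],
) -> List[PafRecord]:
    """One PAF record per chain.

    Residue-matches is the sum of anchor spans; block length is the longer
    of the two spanned intervals.  Mapping quality is
    ``floor(40 * (1 - s2/s1))`` clamped to [0, 60], where s1 is the chain's
    own score and s2 the best score among the query's other chains (0 if
    none) -- deterministic and monotone in score separation.
    """
    records: List[PafRecord] = []
    scores = sorted((c.score for c in chains), reverse=True)
    for chain in chains:
        others = [s for s in scores]
        others.remove(chain.score)
        s2 = others[0] if others else 0
        mapq = int(math.floor(40.0 * (1.0 - s2 / chain.score))) if chain.score > 0 else 0
        mapq = max(0, min(60, mapq))
        q_span = chain.q_end - chain.q_start
        t_span = chain.t_end - chain.t_start
        records.append(
            PafRecord(
                query_name=query_name,
                query_len=query_len,
                query_start=chain.q_start,
                query_end=chain.q_end,
                strand="+" if chain.strand_pair == SAME else "-",
                target_name=chain.target_id,
                target_len=target_lengths[chain.target_id],
                target_start=chain.t_start,
                target_end=chain.t_end,
                residue_matches=chain.matched_bases,
                block_len=max(q_span, t_span),
                mapq=mapq,
                tags=(("cm", "i", len(chain.anchors)), ("s1", "i", chain.score)),
            )
        )
    return records
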