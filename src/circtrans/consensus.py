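"""Multi-caller consensus over back-splice junction calls.

circRNA callers disagree substantially; the standard remedy is to keep
only circles reported by at least k of n tools (here, 2 of 3 by default).
Identity is (chrom, start, end, strand) — strand is part of the key
because antisense circles are distinct molecules. An optional ``slack``
allows a few nucleotides of boundary wobble between callers; the default
is exact matching.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Dict, List, Sequence, Tuple

from .types import BackspliceJunction, ConsensusCircRNA


def build_consensus(
    calls: Sequence[BackspliceJunction],
    min_callers: int = 2,
    slack: int = 0,
) -> List[ConsensusCircRNA]:
    """Intersect junction calls and keep circles seen by >= min_callers tools.

    Calls are grouped by exact (chrom, start, end, strand) when slack=0,
    else into clusters whose pairwise start and end differences are all
    <= slack. A caller counts once per group no matter how many duplicate
    rows it contributed (its highest read count is used). Canonical
    coordinates of a slack cluster are those of the highest-read call,
    ties broken by smallest (start, end). Output is sorted by
    (chrom, start, end, strand).
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    if slack < 0:
        raise ValueError("slack must be >= 0")

    if slack == 0:
        groups = _group_exact(calls)
    else:
        groups = _group_with_slack(calls, slack)

    out: List[ConsensusCircRNA] = []
    for members in groups:
        # collapse duplicates within a caller: keep its best-supported row
        per_caller: Dict[str, int] = {}
        for j in members:
            caller = j.caller_id or "unknown"
            reads = j.junction_reads or 0
            per_caller[caller] = max(per_caller.get(caller, 0), reads)
        if len(per_caller) < min_callers:
            continue
        canonical = _canonical_call(members)
        junction = BackspliceJunction(
            chrom=canonical.chrom,
            start=canonical.start,
            end=canonical.end,
            strand=canonical.strand,
            caller_id=None,
            junction_reads=None,
        )
        out.append(
            ConsensusCircRNA(
                junction=junction,
                supporting_callers=frozenset(per_caller),
                total_junction_reads=sum(per_caller.values()),
            )
        )
    out.sort(key=lambda r: r.junction.key)
    return out


def _group_exact(
    calls: Sequence[BackspliceJunction],
) -> List[List[BackspliceJunction]]:
    groups: "OrderedDict[Tuple, List[BackspliceJunction]]" = OrderedDict()
    for j in calls:
        groups.setdefault(j.key, []).append(j)
    return list(groups.values())


def _group_with_slack(
    calls: Sequence[BackspliceJunction], slack: int
) -> List[List[BackspliceJunction]]:
    """Greedy complete-linkage clustering per (chrom, strand).

    Calls are visited in sorted order; each joins the first cluster whose
    every member lies within ``slack`` of it at both boundaries, so all
    pairwise differences in a cluster stay bounded. Sorting first makes
    the result independent of input order.
    """
    by_group: Dict[Tuple[str, str], List[BackspliceJunction]] = {}
    for j in calls:
        by_group.setdefault((j.chrom, j.strand), []).append(j)

    clusters: List[List[BackspliceJunction]] = []
    for key in sorted(by_group):
        pending = sorted(
            by_group[key],
            key=lambda j: (j.start, j.end, j.caller_id or "", j.junction_reads or 0),
        )
        local: List[List[BackspliceJunction]] = []
        for j in pending:
            placed = False
            for cluster in local:
                if all(
                    abs(j.start - m.start) <= slack and abs(j.end - m.end) <= slack
                    for m in cluster
                ):
                    cluster.append(j)
                    placed = True
                    break
            if not placed:
                local.append([j])
        clusters.extend(local)
    return clusters


def _canonical_call(members: Sequence[BackspliceJunction]) -> BackspliceJunction:
    """Highest-read call; ties -> lexicographically smallest (start, end)."""
    return min(
        members,
        key=lambda j: (-(j.junction_reads or 0), j.start, j.end),
    )
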