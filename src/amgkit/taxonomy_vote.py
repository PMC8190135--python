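"""Viral taxonomy assignment by hierarchical bitscore-weighted voting.

A contig's proteins are searched against a labelled reference database
(externally; the hit table is the input here).  Rather than recruiting the
most *common* reference taxon, the assigner hierarchically selects the most
*likely* one: at each rank the taxon with the greatest summed bitscore wins,
and lower ranks are chosen only among hits consistent with the winning
higher rank.  Ranks supported by fewer than ``min_support`` of the contig's
proteins are reported as unknown.

A simplified greedy dereplication (k-mer containment, longest first) stands
in for external genome dereplication at 95% identity / 90% coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RefHit",
    "TaxonomyCall",
    "UNKNOWN",
    "dereplicate_refs",
    "best_hits_per_protein",
    "assign_taxonomy",
    "summarize_taxonomy",
]

UNKNOWN = "unknown"
_RANKS = ("order", "family", "subfamily")


@dataclass(frozen=True)
class RefHit:
    query_protein_id: str
    order: str
    family: str
    subfamily: str
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise ValueError("bitscore must be positive")

    def rank_value(self, rank: str) -> str:
        return getattr(self, rank)


@dataclass(frozen=True)
class TaxonomyCall:
    contig_id: str
    order: str
    family: str
    subfamily: str
    support: Mapping[str, float]  # rank -> fraction of proteins voting


# ---------------------------------------------------------------------------
# Reference dereplication
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def dereplicate_refs(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.90,
    k: int = 15,
) -> list[str]:
    """Greedy longest-first dereplication via k-mer containment.

    A sequence is absorbed by an existing representative when the fraction
    of its distinct k-mers found in the representative reaches
    ``coverage_threshold * identity_threshold**k`` — the expected k-mer
    survival when ``coverage_threshold`` of the shorter sequence aligns at
    ``identity_threshold`` per-base identity.  Returns representative ids
    in the order they were founded.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        return []
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    min_containment = coverage_threshold * identity_threshold**k
    reps: list[tuple[str, set[str]]] = []
    for name, seq in items:
        km = _kmers(seq, k)
        absorbed = False
        for _rep_name, rep_km in reps:
            if not km:
                break
            containment = len(km & rep_km) / len(km)
            if containment >= min_containment:
                absorbed = True
                break
        if not absorbed:
            reps.append((name, km))
    return [name for name, _ in reps]


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

def best_hits_per_protein(hits: Iterable[RefHit]) -> list[RefHit]:
    """Reduce to each protein's single best hit (highest bitscore; ties by
    lexicographic taxonomy for determinism)."""
    best: dict[str, RefHit] = {}
    for hit in hits:
        cur = best.get(hit.query_protein_id)
        if (
            cur is None
            or hit.bitscore > cur.bitscore
            or (
                hit.bitscore == cur.bitscore
                and (hit.order, hit.family, hit.subfamily)
                < (cur.order, cur.family, cur.subfamily)
            )
        ):
            best[hit.query_protein_id] = hit
    return [best[k] for k in sorted(best)]


def _vote_rank(
    hits: Sequence[RefHit],
    rank: str,
    n_proteins: int,
    min_support: float,
) -> tuple[str, float, list[RefHit]]:
    """One rank election: returns (winner, support, consistent hits)."""
    groups: dict[str, list[RefHit]] = {}
    for h in hits:
        value = h.rank_value(rank)
        if value and value != UNKNOWN:
            groups.setdefault(value, []).append(h)
    if not groups:
        return UNKNOWN, 0.0, []

    def key(value: str) -> tuple[float, float, list[str]]:
        members = groups[value]
        total = sum(h.bitscore for h in members)
        mean = total / len(members)
        # lexicographically smaller name wins ties -> negate by sort trick
        return (total, mean, value)

    # max by summed bitscore, tie -> higher mean, tie -> lexicographic first
    winner = sorted(
        groups, key=lambda v: (-key(v)[0], -key(v)[1], v)
    )[0]
    voters = groups[winner]
    support = len(voters) / n_proteins if n_proteins else 0.0
    if support < min_support:
        return UNKNOWN, support, []
    return winner, support, voters


def assign_taxonomy(
    hits: Iterable[RefHit],
    contig_id: str,
    n_proteins: int | None = None,
    min_support: float = 0.10,
) -> TaxonomyCall:
    """Hierarchical most-likely taxonomy for one contig's hit set.

    ``n_proteins`` is the contig's protein count used for support fractions;
    it defaults to the number of proteins with at least one hit.  The family
    election only considers best hits whose order matches the elected order,
    and likewise for subfamily within family, so calls are hierarchically
    consistent by construction.
    """
    best = best_hits_per_protein(hits)
    total = n_proteins if n_proteins is not None else len(best)
    if not best or total == 0:
        return TaxonomyCall(
            contig_id, UNKNOWN, UNKNOWN, UNKNOWN,
            {r: 0.0 for r in _RANKS},
        )
    calls: dict[str, str] = {}
    support: dict[str, float] = {}
    pool: Sequence[RefHit] = best
    for rank in _RANKS:
        winner, frac, voters = _vote_rank(pool, rank, total, min_support)
        calls[rank] = winner
        support[rank] = frac
        if winner == UNKNOWN:
            # lower ranks cannot be consistent with an unknown parent
            for lower in _RANKS[_RANKS.index(rank) + 1 :]:
                calls[lower] = UNKNOWN
                support[lower] = 0.0
            break
        pool = voters
    return TaxonomyCall(
        contig_id=contig_id,
        order=calls["order"],
        family=calls["family"],
        subfamily=calls["subfamily"],
        support=support,
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _round_half_away(x: float, ndigits: int = 0) -> float:
    scale = 10**ndigits
    shifted = x * scale
    rounded = int(shifted + 0.5) if shifted >= 0 else -int(-shifted + 0.5)
    return rounded / scale


def summarize_taxonomy(calls: Sequence[TaxonomyCall]) -> pd.DataFrame:
    """Per-family counts and percentages over a contig set.

    Percentages are rounded half away from zero to the nearest integer;
    families below 2% keep one decimal place.
    """
    if not calls:
        raise ValueError("empty call set")
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.family] = counts.get(c.family, 0) + 1
    total = len(calls)
    rows = []
    for family in sorted(counts, key=lambda f: (-counts[f], f)):
        pct = 100.0 * counts[family] / total
        display = _round_half_away(pct, 1) if pct < 2.0 else _round_half_away(pct)
        rows.append(
            {
                "family": family,
                "count": counts[family],
                "percentage": display,
            }
        )
    return pd.DataFrame(rows, columns=["family", "count", "percentage"])
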