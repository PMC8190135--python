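"""Greedy protein clustering and grouping statistics.

Emulates centroid-based sequence clustering at 30% identity and 60%
bidirectional coverage: proteins are processed longest-first, each joining
the first existing centroid it matches or founding a new cluster.  Retained
clusters must span at least two distinct source genomes (the main analysis)
or contain at least two members (the randomized subsample validation).

The headline statistic is clusters-per-protein: the number of retained
clusters divided by the total protein count, a size-robust proxy for how
much protein-family diversity a genome set carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinSeq",
    "Cluster",
    "ClusterSet",
    "ClusterParams",
    "pairwise_identity",
    "cluster_proteins",
    "grouping_stats",
    "subsample_validation",
    "parse_genome_protein_id",
]


@dataclass(frozen=True)
class ProteinSeq:
    protein_id: str
    genome_id: str
    sequence: str


def parse_genome_protein_id(header: str) -> tuple[str, str]:
    """Split a ``genomeID|proteinID`` FASTA header."""
    if "|" not in header:
        raise ValueError(f"header {header!r} lacks the 'genomeID|proteinID' scheme")
    genome_id, protein_id = header.split("|", 1)
    return genome_id, protein_id


@dataclass(frozen=True)
class ClusterParams:
    min_identity: float = 0.30
    min_coverage: float = 0.60  # bidirectional: both sequences must reach it
    retention_mode: str = "min_distinct_genomes"  # or "min_members"
    retention_threshold: int = 2


@dataclass
class Cluster:
    centroid: ProteinSeq
    members: list[ProteinSeq] = field(default_factory=list)  # includes centroid

    @property
    def genome_ids(self) -> set[str]:
        return {m.genome_id for m in self.members}

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    retained: list[Cluster]
    params: ClusterParams
    n_proteins: int


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> tuple[float, float, float]:
    """Global-alignment identity and mutual coverage of two proteins.

    Identity is identical residues over alignment columns excluding terminal
    gaps; coverage of each sequence is the span of its residues lying inside
    the mutually aligned region over its full length.  Identity is symmetric
    in the two arguments.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    # canonical argument order makes the (possibly degenerate) optimal
    # alignment, and hence the identity, symmetric by construction
    if (len(a), a) > (len(b), b):
        identity, cov_b, cov_a = pairwise_identity(b, a)
        return identity, cov_a, cov_b
    aln = _ALIGNER.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0, 0.0
    sa, sb = str(aln[0]), str(aln[1])
    # trim terminal gap columns: region between first and last aligned column
    cols = len(sa)
    lead = 0
    while lead < cols and (sa[lead] == "-" or sb[lead] == "-"):
        lead += 1
    trail = cols
    while trail > lead and (sa[trail - 1] == "-" or sb[trail - 1] == "-"):
        trail -= 1
    core = range(lead, trail)
    matches = sum(1 for i in core if sa[i] == sb[i] and sa[i] != "-")
    identity = matches / len(core) if len(core) else 0.0
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    return identity, span_a / len(a), span_b / len(b)


def _shares_kmer(a: str, b: str, k: int = 4) -> bool:
    """Cheap alignment-free prefilter: any shared k-mer at all."""
    if len(a) < k or len(b) < k:
        return True  # too short to screen; fall through to alignment
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def cluster_proteins(
    proteins: Sequence[ProteinSeq], params: ClusterParams | None = None
) -> ClusterSet:
    """Greedy incremental clustering with deterministic input ordering.

    Sequences are ordered by (length descending, id ascending); each joins
    the first centroid with identity >= min_identity and both coverages
    >= min_coverage, else founds a new cluster.  The retention filter keeps
    clusters spanning >= 2 genomes (``min_distinct_genomes`` mode) or with
    >= 2 members (``min_members`` mode).
    """
    params = params or ClusterParams()
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.protein_id))
    clusters: list[Cluster] = []
    for prot in ordered:
        placed = False
        for cluster in clusters:
            cseq = cluster.centroid.sequence
            if not _shares_kmer(prot.sequence, cseq):
                continue
            identity, cov_q, cov_c = pairwise_identity(prot.sequence, cseq)
            if (
                identity >= params.min_identity
                and cov_q >= params.min_coverage
                and cov_c >= params.min_coverage
            ):
                cluster.members.append(prot)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid=prot, members=[prot]))

    if params.retention_mode == "min_distinct_genomes":
        retained = [
            c for c in clusters if len(c.genome_ids) >= params.retention_threshold
        ]
    elif params.retention_mode == "min_members":
        retained = [c for c in clusters if c.size >= params.retention_threshold]
    else:
        raise ValueError(f"unknown retention_mode {params.retention_mode!r}")
    return ClusterSet(
        clusters=clusters,
        retained=retained,
        params=params,
        n_proteins=len(ordered),
    )


def grouping_stats(
    n_retained: int | ClusterSet, total_proteins: int | None = None
) -> dict:
    """Clusters-per-protein statistic, rounded to three decimals.

    Accepts either a :class:`ClusterSet` or explicit (n_retained,
    total_proteins) counts.
    """
    if isinstance(n_retained, ClusterSet):
        cs = n_retained
        retained = len(cs.retained)
        total = total_proteins if total_proteins is not None else cs.n_proteins
    else:
        retained = n_retained
        if total_proteins is None:
            raise ValueError("total_proteins required with explicit counts")
        total = total_proteins
    if total < retained:
        raise ValueError("total_proteins smaller than retained cluster count")
    cpp = retained / total if total else 0.0
    return {
        "n_retained": retained,
        "total_proteins": total,
        "clusters_per_protein": round(cpp, 3),
    }


def subsample_validation(
    genomes: Mapping[str, Sequence[ProteinSeq]],
    sample_size: int = 94,
    iterations: int = 100,
    seed: int = 0,
    params: ClusterParams | None = None,
) -> dict:
    """Randomized subsample validation of the grouping procedure.

    Each iteration samples ``sample_size`` genomes without replacement,
    clusters their proteins with minimum-group-size-2 retention, and records
    (protein count, retained clusters, clusters-per-protein).  Returns the
    per-iteration records plus min/max/mean summaries.
    """
    names = sorted(genomes)
    if len(names) < sample_size:
        raise ValueError(
            f"genome set ({len(names)}) smaller than sample_size ({sample_size})"
        )
    params = params or ClusterParams(retention_mode="min_members")
    rng = np.random.default_rng(seed)
    records = []
    for it in range(iterations):
        picked = rng.choice(len(names), size=sample_size, replace=False)
        proteins = [p for i in sorted(picked) for p in genomes[names[i]]]
        cs = cluster_proteins(proteins, params)
        stats = grouping_stats(cs)
        records.append(
            {
                "iteration": it,
                "n_proteins": cs.n_proteins,
                "n_retained": stats["n_retained"],
                "clusters_per_protein": stats["clusters_per_protein"],
            }
        )
    cpps = [r["clusters_per_protein"] for r in records]
    counts = [r["n_proteins"] for r in records]
    retained = [r["n_retained"] for r in records]
    return {
        "iterations": records,
        "summary": {
            "n_proteins": {"min": min(counts), "max": max(counts), "mean": sum(counts) / len(counts)},
            "n_retained": {"min": min(retained), "max": max(retained), "mean": sum(retained) / len(retained)},
            "clusters_per_protein": {"min": min(cpps), "max": max(cpps), "mean": sum(cpps) / len(cpps)},
        },
    }
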