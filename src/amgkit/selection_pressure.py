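"""Codon-aware dN/dS estimation (Nei-Gojobori 1986 counting).

The ratio of nonsynonymous to synonymous substitution rates (dN/dS) below 1
indicates purifying selection: deleterious amino-acid-changing mutations are
removed while silent ones accumulate.  Applied to phage-carried metabolic
genes, dN/dS < 1 is evidence that the phage retains the gene's function.

Counting follows NG86 with equal pathway weighting:

* Per codon, each of the nine single-base neighbors is classified as
  synonymous or nonsynonymous; the synonymous site count of a position is
  the fraction of its three changes that are synonymous.  Changes creating
  stop codons count as nonsynonymous sites.
* Site totals are averaged over the two sequences, so S + N = 3L exactly.
* Between two codons differing at k positions, the k! substitution orders
  are enumerated; synonymous/nonsynonymous steps are averaged with equal
  weight over the pathways that avoid stop-codon intermediates.
* Proportions are Jukes-Cantor corrected: d = -(3/4) ln(1 - 4p/3),
  undefined (saturated) when p >= 3/4.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from math import log
from typing import Callable, Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import CODON_TO_AA, STOP_CODONS, translate

__all__ = [
    "CodonAlignment",
    "DnDsResult",
    "UNDEFINED_DS_ZERO",
    "UNDEFINED_SATURATED",
    "thread_codons",
    "ng86_pair",
    "family_dnds",
    "synonymous_site_fraction",
    "pathway_differences",
]

UNDEFINED_DS_ZERO = "undefined_dS_zero"
UNDEFINED_SATURATED = "undefined_saturated"

_BASES = "ACGT"


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Synonymous site count of one codon (0..3).

    Each position contributes the fraction of its three single-base changes
    that preserve the amino acid; stop-creating changes are nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if neighbor not in STOP_CODONS and CODON_TO_AA[neighbor] == aa:
                syn += 1.0 / 3.0
    return syn


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of a codon pair.

    All substitution orders between the differing positions are enumerated;
    pathways passing through stop-codon intermediates are excluded.  If every
    pathway is blocked by stops (possible only for triple-substitution
    pairs), all pathways are used as a fallback.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        current = codon_a
        syn = nonsyn = 0.0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if CODON_TO_AA.get(nxt, "*") == CODON_TO_AA.get(current, "*"):
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        return syn, nonsyn

    results = [
        r for order in permutations(diff_positions) if (r := walk(order, False))
    ]
    if not results:
        results = [walk(order, True) for order in permutations(diff_positions)]
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


# ---------------------------------------------------------------------------
# Codon threading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """A pair of gapped coding sequences aligned codon-wise.

    Gaps come in multiples of three (one protein gap = one codon gap);
    ungapping either sequence recovers the input CDS exactly.
    """

    gapped_a: str
    gapped_b: str

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped sequences differ in length")
        if len(self.gapped_a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    def codon_columns(self) -> list[tuple[str, str]]:
        """Comparable codon pairs: both sides gap-free and stop-free."""
        out = []
        for i in range(0, len(self.gapped_a), 3):
            ca = self.gapped_a[i : i + 3]
            cb = self.gapped_b[i : i + 3]
            if "-" in ca or "-" in cb:
                continue
            out.append((ca, cb))
        return out


def _strip_terminal_stop(cds: str, protein: str) -> str:
    if len(cds) == 3 * (len(protein) + 1) and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def thread_codons(
    protein_alignment: tuple[str, str], cds_a: str, cds_b: str
) -> CodonAlignment:
    """Expand a gapped protein alignment to its codon alignment.

    Each CDS must translate to its ungapped protein (a trailing stop codon
    is tolerated and trimmed); internal stops are rejected.
    """
    pa, pb = protein_alignment
    gapped: list[str] = []
    for gapped_protein, cds in ((pa, cds_a), (pb, cds_b)):
        protein = gapped_protein.replace("-", "")
        cds = _strip_terminal_stop(cds, protein)
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"CDS length {len(cds)} does not match protein length {len(protein)}"
            )
        translated = translate(cds, trim_stop=False)
        if "*" in translated:
            raise ValueError("CDS contains an internal stop codon")
        if translated != protein:
            raise ValueError("CDS does not translate to the aligned protein")
        chunks = []
        k = 0
        for aa in gapped_protein:
            if aa == "-":
                chunks.append("---")
            else:
                chunks.append(cds[3 * k : 3 * k + 3])
                k += 1
        gapped.append("".join(chunks))
    return CodonAlignment(gapped[0], gapped[1])


# ---------------------------------------------------------------------------
# Pairwise NG86
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DnDsResult:
    n_codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    ratio: float | str  # dN/dS, or an undefined sentinel


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_pair(alignment: CodonAlignment | tuple[str, str]) -> DnDsResult:
    """NG86 dN/dS for one codon-aligned pair.

    Accepts a :class:`CodonAlignment` or a plain (cds_a, cds_b) tuple of
    equal-length, gap-free coding sequences.  ``ratio`` is a float when both
    distances are defined and dS > 0, otherwise a sentinel string
    (:data:`UNDEFINED_DS_ZERO` when dS = 0, :data:`UNDEFINED_SATURATED`
    when either Jukes-Cantor correction saturates).
    """
    if isinstance(alignment, tuple):
        alignment = CodonAlignment(*alignment)
    columns = alignment.codon_columns()
    for ca, cb in columns:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError("stop codon among compared columns")
    if not columns:
        raise ValueError("no comparable codon columns")

    s_a = sum(synonymous_site_fraction(ca) for ca, _ in columns)
    s_b = sum(synonymous_site_fraction(cb) for _, cb in columns)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(columns) - S
    Sd = Nd = 0.0
    for ca, cb in columns:
        syn, nonsyn = pathway_differences(ca, cb)
        Sd += syn
        Nd += nonsyn

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    ratio: float | str
    if dS is None or dN is None:
        ratio = UNDEFINED_SATURATED
    elif dS == 0.0:
        ratio = UNDEFINED_DS_ZERO
    else:
        ratio = dN / dS
    return DnDsResult(
        n_codons=len(columns),
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        ratio=ratio,
    )


# ---------------------------------------------------------------------------
# Family-level driver
# ---------------------------------------------------------------------------

def _default_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_protein_pair(a: str, b: str) -> tuple[str, str]:
    """Global BLOSUM62 protein alignment returning gapped strings."""
    aln = _default_protein_aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def family_dnds(
    cds_by_id: Mapping[str, str],
    protein_aligner: Callable[[str, str], tuple[str, str]] = align_protein_pair,
) -> tuple[pd.DataFrame, dict]:
    """All-pairs dN/dS over one AMG family's coding sequences.

    Each unordered pair is protein-aligned, codon-threaded and scored with
    :func:`ng86_pair`.  The summary reports the mean over defined ratios and
    how many pairs were excluded as sentinels (identical pairs, saturation).
    """
    ids = sorted(cds_by_id)
    if len(ids) < 2:
        raise ValueError("family_dnds needs at least two sequences")
    rows = []
    for id_a, id_b in combinations(ids, 2):
        cds_a, cds_b = cds_by_id[id_a], cds_by_id[id_b]
        prot_a = translate(cds_a)
        prot_b = translate(cds_b)
        pa, pb = protein_aligner(prot_a, prot_b)
        result = ng86_pair(thread_codons((pa, pb), cds_a, cds_b))
        rows.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "n_codons": result.n_codons,
                "S_sites": result.S_sites,
                "N_sites": result.N_sites,
                "Sd": result.Sd,
                "Nd": result.Nd,
                "dS": result.dS,
                "dN": result.dN,
                "ratio": result.ratio,
            }
        )
    table = pd.DataFrame(rows)
    defined = [r for r in table["ratio"] if isinstance(r, float)]
    summary = {
        "n_pairs": len(rows),
        "n_defined": len(defined),
        "n_excluded": len(rows) - len(defined),
        "mean_ratio": sum(defined) / len(defined) if defined else None,
    }
    return table, summary
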