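"""Identification and validation of sulfur-metabolism AMGs on phage contigs.

The five AMG families handled here are the dissimilatory-sulfur enzymes and
carriers found on phage genomes: DsrA and DsrC (reverse sulfite reductase
subunit and sulfur carrier), SoxC and SoxD (sulfane dehydrogenase subunits)
and SoxYZ (fused thiosulfate sulfur carrier).  Each family carries a catalog
of conserved-residue motifs; a candidate AMG protein is validated by the
presence of those residues.

Pattern language
----------------
``UPPERCASE`` letters (other than ``X``) are strictly required residues,
``lowercase`` letters are partially conserved residues (required for a *full*
match but not a *strict* match), and ``x``/``X`` match any residue.

Two checking modes exist:

* ``anchored`` (default): the query is globally aligned to an annotated
  family reference protein (BLOSUM62, gap open 11, extend 1) and the motif
  columns are mapped through the alignment.  This makes single-residue
  motifs (SoxC ``D``, ``R``) checkable and mirrors manual alignment-based
  residue inspection.
* ``scan``: motifs of length >= 2 are searched directly in the query, in
  catalog order and non-overlapping; the reported position is the earliest
  window whose strict residues all match.

DsrC versus TusE
----------------
Functional DsrC requires both conserved cysteines of the C-terminal
``C-x(10)-C`` motif; homologs lacking one or both likely act as TusE
(tRNA-thiolation) proteins.  ``dsrc_class`` records which cysteines are
present and :func:`classify_dsrc` aggregates the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import GeneRecord

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "MotifReport",
    "ReferenceProtein",
    "ContextVerdict",
    "DsrcPartition",
    "AMG_FAMILIES",
    "MOTIF_CATALOG",
    "REFERENCE_PROTEINS",
    "scan_motifs",
    "classify_dsrc",
    "score_viral_context",
    "flag_amg_contamination",
    "extract_neighborhood",
    "find_candidate_amgs",
    "screen_contig",
]

LYSOGENY_TERMS = ("integrase", "recombination", "repressor", "prophage")

MIN_PHAGE_CONTIG_BP = 5_000


@dataclass(frozen=True)
class MotifPattern:
    family: str
    motif_id: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def strict_positions(self) -> list[int]:
        return [
            i
            for i, c in enumerate(self.pattern)
            if c.isupper() and c != "X"
        ]

    @property
    def lowercase_positions(self) -> list[int]:
        return [
            i
            for i, c in enumerate(self.pattern)
            if c.islower() and c != "x"
        ]

    def strict_matches_at(self, protein: str, pos: int) -> bool:
        if pos < 0 or pos + len(self.pattern) > len(protein):
            return False
        return all(
            protein[pos + i] == self.pattern[i].upper()
            for i in self.strict_positions
        )

    def full_matches_at(self, protein: str, pos: int) -> bool:
        return self.strict_matches_at(protein, pos) and all(
            protein[pos + i] == self.pattern[i].upper()
            for i in self.lowercase_positions
        )


def _load_catalog() -> dict[str, list[MotifPattern]]:
    catalog: dict[str, list[MotifPattern]] = {}
    text = (
        resources.files("amgkit").joinpath("data/motif_catalog.tsv").read_text()
    )
    lines = text.strip().split("\n")
    for line in lines[1:]:
        family, motif_id, pattern, _ = line.split("\t")
        catalog.setdefault(family, []).append(MotifPattern(family, motif_id, pattern))
    return catalog


#: built-in catalog: family -> ordered motif list
MOTIF_CATALOG: dict[str, list[MotifPattern]] = _load_catalog()
AMG_FAMILIES: tuple[str, ...] = tuple(MOTIF_CATALOG)


# ---------------------------------------------------------------------------
# Reference proteins for anchored mode (also the planting templates used by
# the synthetic community generator)
# ---------------------------------------------------------------------------

#: filler alphabet free of every strictly required motif residue, so planted
#: motif windows are the only strict matches on a template
_FILLER = "ALVTSNQIFWY"


def _fill(n: int, phase: int = 0) -> str:
    return "".join(_FILLER[(phase + i) % len(_FILLER)] for i in range(n))


@dataclass(frozen=True)
class ReferenceProtein:
    """An annotated family reference: sequence plus motif start positions."""

    family: str
    sequence: str
    motif_positions: Mapping[str, int]  # motif_id -> 0-based start in sequence


def _instantiate(pattern: str, phase: int) -> str:
    out = []
    for i, c in enumerate(pattern):
        if c in "xX":
            out.append(_FILLER[(phase + i) % len(_FILLER)])
        else:
            out.append(c.upper())
    return "".join(out)


def _build_reference(family: str, spacer: int = 12, flank: int = 30) -> ReferenceProtein:
    """Assemble a family reference embedding its motifs in catalog order.

    The two DsrC catalog entries are alternate spellings of one physical
    motif (both span 12 residues with cysteines at offsets 0 and 11), so
    they share a single embedded window.
    """
    motifs = MOTIF_CATALOG[family]
    seq_parts = [_fill(flank)]
    positions: dict[str, int] = {}
    cursor = flank
    placed_window: tuple[int, str] | None = None
    for m in motifs:
        if family == "DsrC" and placed_window is not None:
            positions[m.motif_id] = placed_window[0]
            continue
        inst = _instantiate(m.pattern, phase=cursor)
        positions[m.motif_id] = cursor
        seq_parts.append(inst)
        cursor += len(inst)
        if family == "DsrC":
            placed_window = (positions[m.motif_id], inst)
        seq_parts.append(_fill(spacer, phase=cursor))
        cursor += spacer
    seq_parts.append(_fill(flank - spacer if flank > spacer else flank, phase=cursor))
    return ReferenceProtein(family, "".join(seq_parts), positions)


REFERENCE_PROTEINS: dict[str, ReferenceProtein] = {
    fam: _build_reference(fam) for fam in MOTIF_CATALOG
}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _map_reference_columns(reference: str, query: str) -> dict[int, int]:
    """Map reference positions to query positions via global alignment.

    Positions aligned to a gap in the query are absent from the mapping.
    """
    aln = _ALIGNER.align(reference, query)[0]
    ref_blocks, qry_blocks = aln.aligned
    mapping: dict[int, int] = {}
    for (rs, re_), (qs, _qe) in zip(ref_blocks, qry_blocks):
        for k in range(re_ - rs):
            mapping[rs + k] = qs + k
    return mapping


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifMatch:
    strict_match: bool
    full_match: bool
    position: int | None  # 0-based query position of the motif start

    def __post_init__(self) -> None:
        if self.full_match and not self.strict_match:
            raise ValueError("full_match implies strict_match")


@dataclass
class MotifReport:
    protein_id: str
    family_call: str
    matches: dict[str, MotifMatch]
    dsrc_class: str = "not_applicable"  # both/second_only/first_only/neither
    mode: str = "anchored"

    @property
    def validated(self) -> bool:
        """True when every checkable motif of the family strict-matches."""
        return all(m.strict_match for m in self.matches.values())


_DSRC_CLASSES = ("both", "second_only", "first_only", "neither")


def _dsrc_class_from_cys(first_present: bool, second_present: bool) -> str:
    if first_present and second_present:
        return "both"
    if second_present:
        return "second_only"
    if first_present:
        return "first_only"
    return "neither"


def scan_motifs(
    protein: str,
    family: str,
    mode: str = "anchored",
    reference: ReferenceProtein | None = None,
    protein_id: str = "query",
) -> MotifReport:
    """Check one protein against a family's conserved-residue catalog.

    In scan mode only motifs of length >= 2 are searched (a single wildcard
    residue is meaningless without positional context); they must occur in
    catalog order without overlap.  In anchored mode every motif is checked
    at alignment-mapped columns of the (built-in or supplied) reference.
    """
    protein = protein.upper()
    if not protein:
        raise ValueError("empty protein sequence")
    if family not in MOTIF_CATALOG:
        raise KeyError(f"unknown AMG family {family!r}")
    motifs = MOTIF_CATALOG[family]
    matches: dict[str, MotifMatch] = {}

    if mode == "scan":
        # alternate spellings of one physical motif share a reference start
        # position; they are searched from the same cursor and the cursor
        # advances only once per such group
        ref_positions = REFERENCE_PROTEINS[family].motif_positions
        groups: dict[int, list[MotifPattern]] = {}
        for m in motifs:
            groups.setdefault(ref_positions[m.motif_id], []).append(m)
        cursor = 0
        for _start in sorted(groups):
            group_end = cursor
            for m in groups[_start]:
                if len(m) < 2:
                    continue
                pos = None
                for p in range(cursor, len(protein) - len(m) + 1):
                    if m.strict_matches_at(protein, p):
                        pos = p
                        break
                if pos is None:
                    matches[m.motif_id] = MotifMatch(False, False, None)
                else:
                    matches[m.motif_id] = MotifMatch(
                        True, m.full_matches_at(protein, pos), pos
                    )
                    group_end = max(group_end, pos + len(m))
            cursor = group_end
    elif mode == "anchored":
        ref = reference or REFERENCE_PROTEINS[family]
        colmap = _map_reference_columns(ref.sequence, protein)
        for m in motifs:
            start = ref.motif_positions[m.motif_id]
            mapped = [colmap.get(start + i) for i in range(len(m))]
            strict_ok = all(
                mapped[i] is not None
                and protein[mapped[i]] == m.pattern[i].upper()
                for i in m.strict_positions
            )
            full_ok = strict_ok and all(
                mapped[i] is not None
                and protein[mapped[i]] == m.pattern[i].upper()
                for i in m.lowercase_positions
            )
            matches[m.motif_id] = MotifMatch(strict_ok, full_ok, mapped[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    report = MotifReport(protein_id, family, matches, mode=mode)
    if family == "DsrC":
        report.dsrc_class = _classify_dsrc_protein(protein, mode, reference)
    return report


def _classify_dsrc_protein(
    protein: str, mode: str, reference: ReferenceProtein | None
) -> str:
    """Which of the two conserved C-x(10)-C cysteines does a DsrC carry?"""
    spacing = next(
        m for m in MOTIF_CATALOG["DsrC"] if m.motif_id == "dsrC_cys_spacing"
    )
    span = len(spacing)  # 12: cysteines at offsets 0 and 11
    if mode == "anchored":
        ref = reference or REFERENCE_PROTEINS["DsrC"]
        start = ref.motif_positions["dsrC_cys_spacing"]
        colmap = _map_reference_columns(ref.sequence, protein)
        p1 = colmap.get(start)
        p2 = colmap.get(start + span - 1)
        first = p1 is not None and protein[p1] == "C"
        second = p2 is not None and protein[p2] == "C"
        return _dsrc_class_from_cys(first, second)
    # scan fallback: only the jointly-spaced pattern is locatable without a
    # reference, so a lone cysteine cannot be assigned to first vs second
    for p in range(len(protein) - span + 1):
        if spacing.strict_matches_at(protein, p):
            return "both"
    return "neither" if "C" not in protein else "second_only"


@dataclass(frozen=True)
class DsrcPartition:
    both: int
    second_only: int
    first_only: int
    neither: int

    @property
    def tusE_like(self) -> int:
        """Proteins lacking the full two-cysteine motif (TusE-like)."""
        return self.second_only + self.first_only + self.neither

    @property
    def total(self) -> int:
        return self.both + self.tusE_like


def classify_dsrc(reports: Iterable[MotifReport]) -> DsrcPartition:
    """Partition DsrC-family reports into motif classes and count TusE-like.

    Functional DsrC retains both conserved cysteines; everything else
    (second only / first only / neither) is counted as TusE-like.
    """
    counts = {c: 0 for c in _DSRC_CLASSES}
    for r in reports:
        if r.family_call != "DsrC":
            raise ValueError(f"{r.protein_id}: not a DsrC-family report")
        if r.dsrc_class not in counts:
            raise ValueError(f"{r.protein_id}: dsrc_class not computed")
        counts[r.dsrc_class] += 1
    return DsrcPartition(**counts)


# ---------------------------------------------------------------------------
# Viral-context heuristics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContextVerdict:
    contig_id: str
    verdict: str  # phage / not_phage / ambiguous
    lysogeny_flag: bool
    hallmark_count: int
    viral_like_count: int
    microbial_like_count: int
    unannotated_count: int

    @property
    def n_genes(self) -> int:
        return (
            self.hallmark_count
            + self.viral_like_count
            + self.microbial_like_count
            + self.unannotated_count
        )

    @property
    def unannotated_fraction(self) -> float:
        return self.unannotated_count / self.n_genes if self.n_genes else 0.0


def score_viral_context(
    genes: Sequence[GeneRecord],
    contig_id: str | None = None,
    unannotated_cutoff: float = 0.5,
) -> ContextVerdict:
    """Judge whether a contig's gene content looks phage-like.

    A contig is called ``phage`` when it carries at least one viral hallmark
    gene and either its viral-like annotations outnumber (or tie)
    microbial-like ones or at least half its proteins are unannotated;
    ``not_phage`` when it has no hallmark genes and microbial-like
    annotations dominate; otherwise ``ambiguous``.  The lysogeny flag fires
    on integrase/recombination/repressor/prophage keywords.
    """
    if not genes:
        raise ValueError("no genes supplied")
    cid = contig_id or genes[0].contig_id
    counts = {"viral-hallmark": 0, "viral-like": 0, "microbial-like": 0, "unannotated": 0}
    lysogeny = False
    for g in genes:
        counts[g.annotation_label] += 1
        for term in g.keyword_terms:
            t = term.lower()
            if any(key in t for key in LYSOGENY_TERMS):
                lysogeny = True
    hallmark = counts["viral-hallmark"]
    viral = counts["viral-like"]
    microbial = counts["microbial-like"]
    unann_frac = counts["unannotated"] / len(genes)

    if hallmark >= 1 and (viral >= microbial or unann_frac >= unannotated_cutoff):
        verdict = "phage"
    elif hallmark == 0 and microbial > viral:
        verdict = "not_phage"
    else:
        verdict = "ambiguous"
    return ContextVerdict(
        contig_id=cid,
        verdict=verdict,
        lysogeny_flag=lysogeny,
        hallmark_count=hallmark,
        viral_like_count=viral,
        microbial_like_count=microbial,
        unannotated_count=counts["unannotated"],
    )


def flag_amg_contamination(
    genes: Sequence[GeneRecord],
    amg_index: int,
    window: int = 5,
    microbial_threshold: float = 0.7,
) -> bool:
    """Flag an AMG as possible microbial contamination.

    Requires BOTH a high density of microbial-like annotations in the
    +-``window`` genes around the AMG (the AMG itself excluded) and an
    integrase keyword anywhere on the contig.  Windows truncated by a
    scaffold end are evaluated over the available genes.
    """
    if not 0 <= amg_index < len(genes):
        raise IndexError(f"amg_index {amg_index} out of range")
    lo = max(0, amg_index - window)
    hi = min(len(genes), amg_index + window + 1)
    neighbors = [g for i, g in enumerate(genes[lo:hi], start=lo) if i != amg_index]
    if not neighbors:
        return False
    microbial_frac = sum(
        1 for g in neighbors if g.annotation_label == "microbial-like"
    ) / len(neighbors)
    integrase = any(
        "integrase" in term.lower() for g in genes for term in g.keyword_terms
    )
    return microbial_frac >= microbial_threshold and integrase


def extract_neighborhood(
    genes: Sequence[GeneRecord], amg_index: int, k: int = 5
) -> list[GeneRecord] | None:
    """Return the 2k+1-gene window centered on an AMG, or None.

    AMGs within ``k`` genes of a scaffold end are rejected (None) because a
    truncated neighborhood cannot be compared across contigs.
    """
    if not 0 <= amg_index < len(genes):
        raise IndexError(f"amg_index {amg_index} out of range")
    if amg_index < k or amg_index + k >= len(genes):
        return None
    return list(genes[amg_index - k : amg_index + k + 1])


# ---------------------------------------------------------------------------
# Contig-level screening driver
# ---------------------------------------------------------------------------

_FAMILY_KEYWORDS = {fam.lower(): fam for fam in AMG_FAMILIES}


def find_candidate_amgs(genes: Sequence[GeneRecord]) -> list[tuple[int, str]]:
    """Locate candidate AMGs from annotation keywords.

    A gene is a candidate when one of its keyword terms names an AMG family
    (case-insensitive, e.g. ``dsrA`` or ``soxYZ sulfur carrier``).  Returns
    (gene_index_in_list, family) pairs.
    """
    out: list[tuple[int, str]] = []
    for i, g in enumerate(genes):
        for term in g.keyword_terms:
            words = term.lower().split()
            for fam_lower, fam in _FAMILY_KEYWORDS.items():
                if fam_lower in words:
                    out.append((i, fam))
                    break
            else:
                continue
            break
    return out


def screen_contig(
    genes: Sequence[GeneRecord],
    contig_length: int,
    mode: str = "anchored",
    min_contig_bp: int = MIN_PHAGE_CONTIG_BP,
) -> tuple[ContextVerdict, list[dict]] | None:
    """Screen one contig: context verdict plus per-AMG validation rows.

    Contigs shorter than ``min_contig_bp`` are rejected (None), mirroring
    the >=5 kb inclusion filter for viral scaffolds.
    """
    if contig_length < min_contig_bp:
        return None
    verdict = score_viral_context(genes)
    rows: list[dict] = []
    for idx, family in find_candidate_amgs(genes):
        gene = genes[idx]
        report = scan_motifs(gene.protein, family, mode=mode, protein_id=gene.gene_id)
        neighborhood = extract_neighborhood(genes, idx)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "contig_id": gene.contig_id,
                "family": family,
                "validated": report.validated,
                "dsrc_class": report.dsrc_class,
                "contamination_flag": flag_amg_contamination(genes, idx),
                "lysogeny_flag": verdict.lysogeny_flag,
                "verdict": verdict.verdict,
                "neighborhood_ok": neighborhood is not None,
                "report": report,
            }
        )
    return verdict, rows
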