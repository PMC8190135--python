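"""Sequence and table I/O plus a naive ORF finder.

Conventions used throughout the package:

* Gene coordinates are 1-based inclusive (GFF3 convention).  ``gene_index``
  is the 0-based order of a gene along its contig and is what all
  window/neighborhood arithmetic uses.
* Nucleotide alphabets are restricted to ``ACGTN``; sequences are upper-cased
  on ingest.  ``N`` translates to ``X`` and never satisfies a motif residue.
* The TSV gene-table dialect is the package's canonical round-trip format;
  GFF3 is emitted for interoperability with genome browsers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "ContigRecord",
    "GeneRecord",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "write_gff3",
    "parse_newick",
    "PhyloTree",
    "find_orfs",
    "translate",
    "reverse_complement",
]

_NT_ALPHABET = set("ACGTN")
_TABLE11 = unambiguous_dna_by_id[11]

#: codon -> amino acid for translation table 11 ('*' marks stops).
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, trim_stop: bool = True) -> str:
    """Translate a CDS with table 11; codons containing N become X."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aas.append(CODON_TO_AA.get(codon, "X"))
    protein = "".join(aas)
    if trim_stop and protein.endswith("*"):
        protein = protein[:-1]
    return protein


@dataclass(frozen=True)
class ContigRecord:
    """A nucleotide scaffold (phage contig or host genome fragment)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(seq) - _NT_ALPHABET
        if bad:
            raise ValueError(f"contig {self.id!r}: illegal characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    """A called gene on a contig with its sequences and annotation labels."""

    contig_id: str
    gene_index: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    protein: str = ""
    cds: str = ""
    annotation_label: str = "unannotated"
    keyword_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.annotation_label not in {
            "viral-hallmark",
            "viral-like",
            "microbial-like",
            "unannotated",
        }:
            raise ValueError(f"unknown annotation label {self.annotation_label!r}")

    @property
    def gene_id(self) -> str:
        return f"{self.contig_id}_{self.gene_index + 1}"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read FASTA into :class:`ContigRecord` objects (upper-cased).

    Duplicate ids and empty sequences are rejected.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        if header in seen:
            raise ValueError(f"duplicate FASTA id {header!r}")
        seen.add(header)
        records.append(ContigRecord(header, "".join(chunks)))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            elif line:
                chunks.append(line.strip())
    _flush()
    return records


def read_fasta_proteins(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA as an id -> sequence mapping (upper-cased)."""
    out: dict[str, str] = {}
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    if header in out:
                        raise ValueError(f"duplicate FASTA id {header!r}")
                    out[header] = "".join(chunks).upper()
                header = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.strip())
    if header is not None:
        if header in out:
            raise ValueError(f"duplicate FASTA id {header!r}")
        out[header] = "".join(chunks).upper()
    return out


def write_fasta(
    records: Iterable[ContigRecord] | dict[str, str],
    path: str | Path,
    width: int = 60,
) -> Path:
    """Write sequences as FASTA with fixed-width line wrapping."""
    if isinstance(records, dict):
        items = list(records.items())
    else:
        items = [(r.id, r.sequence) for r in records]
    seen: set[str] = set()
    with open(path, "w") as fh:
        for name, seq in items:
            if name in seen:
                raise ValueError(f"duplicate FASTA id {name!r}")
            if not seq:
                raise ValueError(f"empty sequence for id {name!r}")
            seen.add(name)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = [
    "contig_id",
    "gene_index",
    "start",
    "end",
    "strand",
    "annotation_label",
    "keyword_terms",
    "protein",
    "cds",
]


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> Path:
    """Write genes as a TSV with a header row (the canonical dialect)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        str(g.gene_index),
                        str(g.start),
                        str(g.end),
                        g.strand,
                        g.annotation_label,
                        ";".join(sorted(g.keyword_terms)),
                        g.protein,
                        g.cds,
                    ]
                )
                + "\n"
            )
    return Path(path)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLUMNS:
            raise ValueError(f"unexpected gene-table columns: {header}")
        for line in fh:
            row = line.rstrip("\n").split("\t")
            rec = dict(zip(_GENE_COLUMNS, row))
            genes.append(
                GeneRecord(
                    contig_id=rec["contig_id"],
                    gene_index=int(rec["gene_index"]),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    strand=rec["strand"],
                    annotation_label=rec["annotation_label"],
                    keyword_terms=set(t for t in rec["keyword_terms"].split(";") if t),
                    protein=rec["protein"],
                    cds=rec["cds"],
                )
            )
    return genes


def write_gff3(genes: Sequence[GeneRecord], path: str | Path) -> Path:
    """Emit GFF3 (coordinates 1-based inclusive, CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};annotation_label={g.annotation_label}"
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "amgkit",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )
    return Path(path)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """Thin wrapper over a dendropy tree exposing leaf queries.

    Topological distance counts edges on the leaf-to-leaf path; patristic
    distance sums branch lengths (missing lengths count as 0).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._pdm = tree.phylogenetic_distance_matrix()
        self._leaves = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._leaves)

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def _taxon(self, label: str) -> dendropy.Taxon:
        try:
            return self._leaves[label]
        except KeyError:
            raise KeyError(f"no leaf labelled {label!r}") from None

    def topological_distance(self, a: str, b: str) -> int:
        return int(self._pdm.path_edge_count(self._taxon(a), self._taxon(b)))

    def branch_length_distance(self, a: str, b: str) -> float:
        return float(self._pdm.patristic_distance(self._taxon(a), self._taxon(b)))


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick tree string."""
    if text.count("(") != text.count(")"):
        raise ValueError("malformed Newick: unbalanced parentheses")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Naive ORF finder
# ---------------------------------------------------------------------------

def find_orfs(contig: ContigRecord, min_aa: int = 60) -> list[GeneRecord]:
    """Find maximal ATG->stop open reading frames on both strands.

    Stand-in for an external gene caller: translation table 11, ATG start
    codons only, an ORF is the first ATG after the previous in-frame stop
    through its stop codon.  Coordinates are 1-based inclusive on the forward
    strand; ORFs without a stop codon before the contig end are discarded.
    Results are ordered by start coordinate, then strand.
    """
    seq = contig.sequence
    n = len(seq)
    orfs: list[tuple[int, int, str, str]] = []  # start, end, strand, cds

    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            start_pos: int | None = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if start_pos is not None:
                        cds = s[start_pos : i + 3]
                        if len(cds) // 3 - 1 >= min_aa:
                            if strand == "+":
                                orfs.append((start_pos + 1, i + 3, strand, cds))
                            else:
                                orfs.append((n - (i + 3) + 1, n - start_pos, strand, cds))
                        start_pos = None
                elif codon == "ATG" and start_pos is None:
                    start_pos = i

    orfs.sort(key=lambda t: (t[0], t[1], t[2]))
    genes = []
    for idx, (start, end, strand, cds) in enumerate(orfs):
        genes.append(
            GeneRecord(
                contig_id=contig.id,
                gene_index=idx,
                start=start,
                end=end,
                strand=strand,
                protein=translate(cds),
                cds=cds,
            )
        )
    return genes
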