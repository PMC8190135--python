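"""Synthetic phage/host community generator with known ground truth.

Every input the analysis pipeline consumes can be produced here: phage
contigs (>=5 kb) carrying 1-4 sulfur-metabolism AMGs inside an auxiliary
cassette, host genome fragments (>=10 kb) with sulfur-operon homologs and
CRISPR arrays, per-gene read-coverage tables generated under a virocell
community model, two-condition transcript counts, and codon-sequence pairs
evolved under a chosen dN/dS.  A :class:`TruthManifest` records what was
planted so downstream modules can be scored against ground truth.

Community model
---------------
Every cell contributes one coverage unit per host gene.  A fraction ``v``
of cells are virocells (phage-infected); each virocell contributes ``R``
units per phage gene (phage genome replication factor).  Hence the expected
per-gene coverage is ``c0`` for host genes and ``c0*v*R`` for phage genes,
and the community phage:total gene-coverage ratio for a family with equal
phage/host gene counts is ``vR/(vR+1)``.  Noise is multiplicative lognormal.

Randomness
----------
All randomness derives from one master seed.  Each stage draws from its own
numbered :class:`numpy.random.SeedSequence` stream
(``SeedSequence(seed, spawn_key=(stream,))``) so that, e.g., regenerating
coverage does not perturb genome synthesis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .amg_screen import AMG_FAMILIES, REFERENCE_PROTEINS, _FILLER
from .seq_io import (
    CODON_TO_AA,
    ContigRecord,
    GeneRecord,
    STOP_CODONS,
    translate,
    write_fasta,
    write_gene_table,
    write_gff3,
)

__all__ = [
    "SimConfig",
    "TruthManifest",
    "GeneTruth",
    "PairTruth",
    "SpacerTruth",
    "Community",
    "simulate_community",
    "simulate_coverage",
    "simulate_transcripts",
    "evolve_codon_pair",
    "plant_crispr_array",
    "write_community",
]

# per-stage RNG stream indices under the master seed
_STREAMS = {"community": 0, "coverage": 1, "transcripts": 2, "codons": 3, "crispr": 4}

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*")
)

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _CODONS_BY_AA.setdefault(CODON_TO_AA[_codon], []).append(_codon)

_BASES = "ACGT"


def stream_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage generator derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stage],))
    )


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic community.

    Defaults mirror the conditions of the source study where stated:
    phage contigs of at least 5 kb carrying 1-4 AMGs, host fragments of at
    least 10 kb, AMG family frequencies matching the observed census
    (dsrC-family carriers dominate), a marine virocell fraction of 16%, and
    a hydrothermal:background expression fold of 15.
    """

    seed: int = 0
    n_hosts: int = 4
    n_phages: int = 8
    phage_len_range: tuple[int, int] = (5_000, 40_000)
    host_len_range: tuple[int, int] = (10_000, 60_000)
    amg_per_phage_range: tuple[int, int] = (1, 4)
    amg_family_weights: dict[str, float] = field(
        default_factory=lambda: {
            "DsrA": 0.17,
            "DsrC": 0.62,
            "SoxYZ": 0.19,
            "SoxC": 0.01,
            "SoxD": 0.01,
        }
    )
    dsrc_class_weights: dict[str, float] = field(
        default_factory=lambda: {"both": 1.0}
    )
    motif_conservation_prob: float = 1.0  # partially conserved positions kept
    virocell_fraction: float = 0.16  # v
    replication_factor: float = 10.0  # R
    coverage_baseline: float = 10.0  # c0, depth units per cell
    coverage_noise: float = 0.3  # lognormal sigma; 0 = noise-free
    n_samples: int = 3
    condition_fold: float = 15.0  # hydrothermal : background multiplier
    transcript_baseline: float = 50.0  # background Poisson mean per gene
    library_size: int = 1_000_000  # mapped reads per condition library
    omega: float = 0.2  # target dN/dS for codon evolution
    divergence: float = 0.2  # accepted substitutions per codon
    crispr_spacers_per_host: int = 3
    crispr_repeat_len: int = 25
    crispr_spacer_len: int = 32
    crispr_mismatches: int = 0
    minus_strand_prob: float = 0.2  # for filler genes

    def __post_init__(self) -> None:
        for name in ("phage_len_range", "host_len_range", "amg_per_phage_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if not 0.0 <= self.virocell_fraction <= 1.0:
            raise ValueError("virocell_fraction must be in [0, 1]")
        if self.replication_factor <= 0:
            raise ValueError("replication_factor must be positive")
        if self.condition_fold <= 0:
            raise ValueError("condition_fold must be positive")
        total = sum(self.amg_family_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"amg_family_weights sum to {total}, expected 1")
        unknown = set(self.amg_family_weights) - set(AMG_FAMILIES)
        if unknown:
            raise ValueError(f"unknown AMG families in weights: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class GeneTruth:
    gene_id: str
    contig_id: str
    role: str  # phage / host
    family: str | None = None  # AMG or host-homolog family
    planted_amg: bool = False
    dsrc_class: str | None = None


@dataclass
class PairTruth:
    phage_gene_id: str
    host_gene_id: str
    family: str


@dataclass
class SpacerTruth:
    host_id: str
    phage_id: str
    spacer_index: int
    sequence: str
    mismatches: int


@dataclass
class TruthManifest:
    contig_roles: dict[str, str] = field(default_factory=dict)
    genes: list[GeneTruth] = field(default_factory=list)
    pairs: list[PairTruth] = field(default_factory=list)
    spacer_links: list[SpacerTruth] = field(default_factory=list)
    samples: dict[str, dict[str, float]] = field(default_factory=dict)  # v, R

    def family_genes(self) -> list[GeneTruth]:
        return [g for g in self.genes if g.family is not None]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class Community:
    contigs: list[ContigRecord]
    genes: dict[str, list[GeneRecord]]  # contig_id -> ordered gene calls
    manifest: TruthManifest

    def all_genes(self) -> list[GeneRecord]:
        return [g for cid in sorted(self.genes) for g in self.genes[cid]]


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def _random_filler_protein(rng: np.random.Generator, n_aa: int) -> str:
    """A planted protein drawn from the motif-free filler alphabet."""
    body = rng.choice(list(_FILLER), size=n_aa - 1)
    return "M" + "".join(body)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Pick uniform synonymous codons; append a random stop codon."""
    codons = [
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein
    ]
    stops = sorted(STOP_CODONS)
    codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


def _planted_amg_protein(
    rng: np.random.Generator,
    family: str,
    conservation_prob: float,
    dsrc_class: str = "both",
) -> str:
    """Instantiate a family template: strict residues always, partially
    conserved residues with probability ``conservation_prob``, wildcard
    positions randomized over the filler alphabet."""
    ref = REFERENCE_PROTEINS[family]
    from .amg_screen import MOTIF_CATALOG  # local import to avoid cycle noise

    seq = list(ref.sequence)
    strict: set[int] = set()
    lowercase: set[int] = set()
    wildcard: set[int] = set()
    for motif in MOTIF_CATALOG[family]:
        start = ref.motif_positions[motif.motif_id]
        for i, c in enumerate(motif.pattern):
            pos = start + i
            if c in "xX":
                wildcard.add(pos)
            elif c.isupper():
                strict.add(pos)
            else:
                lowercase.add(pos)
    wildcard -= strict | lowercase
    for pos in range(len(seq)):
        if pos in strict:
            continue
        if pos in lowercase:
            if rng.random() >= conservation_prob:
                seq[pos] = _FILLER[rng.integers(len(_FILLER))]
        else:
            # filler and wildcard positions: resample for sequence diversity
            if rng.random() < 0.3:
                seq[pos] = _FILLER[rng.integers(len(_FILLER))]
    if family == "DsrC" and dsrc_class != "both":
        start = ref.motif_positions["dsrC_cys_spacing"]
        first_c, second_c = start, start + 11
        if dsrc_class in ("second_only", "neither"):
            seq[first_c] = "A"
        if dsrc_class in ("first_only", "neither"):
            seq[second_c] = "A"
    protein = "".join(seq)
    return "M" + protein if not protein.startswith("M") else protein


def _mutate_protein(
    rng: np.random.Generator, protein: str, rate: float = 0.05
) -> str:
    """Host homolog: light filler-alphabet point mutation of an AMG protein."""
    seq = list(protein)
    for i in range(1, len(seq)):
        if rng.random() < rate:
            seq[i] = _FILLER[rng.integers(len(_FILLER))]
    return "".join(seq)


@dataclass
class _GenePlan:
    protein: str
    label: str
    keywords: set[str]
    family: str | None = None
    planted_amg: bool = False
    dsrc_class: str | None = None
    strand: str = "+"


def _assemble_contig(
    contig_id: str,
    plans: Sequence[_GenePlan],
    rng: np.random.Generator,
    target_len: int,
    reserve_tail: int = 0,
) -> tuple[str, list[GeneRecord]]:
    """Lay planned genes on a contig separated by stop-rich TAA spacers.

    Returns the sequence (padded to ``target_len`` minus ``reserve_tail``
    of trailing space left for, e.g., a CRISPR array) and the gene calls.
    """
    from .seq_io import reverse_complement

    parts: list[str] = []
    genes: list[GeneRecord] = []
    cursor = 0
    for idx, plan in enumerate(plans):
        spacer = "TAA" * int(rng.integers(4, 9))
        parts.append(spacer)
        cursor += len(spacer)
        cds = _reverse_translate(rng, plan.protein)
        embedded = cds if plan.strand == "+" else reverse_complement(cds)
        genes.append(
            GeneRecord(
                contig_id=contig_id,
                gene_index=idx,
                start=cursor + 1,
                end=cursor + len(cds),
                strand=plan.strand,
                protein=plan.protein,
                cds=cds,
                annotation_label=plan.label,
                keyword_terms=set(plan.keywords),
            )
        )
        parts.append(embedded)
        cursor += len(embedded)
    body = "".join(parts)
    pad_to = target_len - reserve_tail
    if len(body) > pad_to:
        raise ValueError(
            f"{contig_id}: planned genes ({len(body)} bp) exceed target {pad_to} bp"
        )
    pad = "TAA" * ((pad_to - len(body)) // 3 + 1)
    return (body + pad)[:pad_to], genes


def _plan_phage_genes(
    rng: np.random.Generator, cfg: SimConfig, target_len: int
) -> list[_GenePlan]:
    n_amgs = int(rng.integers(cfg.amg_per_phage_range[0], cfg.amg_per_phage_range[1] + 1))
    families = list(cfg.amg_family_weights)
    weights = np.array([cfg.amg_family_weights[f] for f in families])
    chosen = [families[i] for i in rng.choice(len(families), size=n_amgs, p=weights)]

    dsrc_classes = sorted(cfg.dsrc_class_weights)
    dsrc_w = np.array([cfg.dsrc_class_weights[c] for c in dsrc_classes])
    dsrc_w = dsrc_w / dsrc_w.sum()

    amg_plans: list[_GenePlan] = []
    for fam in chosen:
        klass = (
            dsrc_classes[rng.choice(len(dsrc_classes), p=dsrc_w)]
            if fam == "DsrC"
            else None
        )
        protein = _planted_amg_protein(
            rng, fam, cfg.motif_conservation_prob, dsrc_class=klass or "both"
        )
        amg_plans.append(
            _GenePlan(
                protein=protein,
                label="microbial-like",
                keywords={f"{fam} sulfur metabolism"},
                family=fam,
                planted_amg=True,
                dsrc_class=klass,
            )
        )

    # mandatory viral context: one hallmark plus enough viral-like genes to
    # outnumber the microbial-like AMG annotations
    hallmark = _GenePlan(
        protein=_random_filler_protein(rng, int(rng.integers(150, 201))),
        label="viral-hallmark",
        keywords={"terminase large subunit"},
    )
    viral_like = [
        _GenePlan(
            protein=_random_filler_protein(rng, int(rng.integers(80, 151))),
            label="viral-like",
            keywords={"phage structural protein"},
        )
        for _ in range(n_amgs)
    ]

    budget = target_len - sum(
        3 * (len(p.protein) + 1) + 27 for p in amg_plans + [hallmark] + viral_like
    )
    extras: list[_GenePlan] = []
    while budget > 3 * 81 + 27:
        n_aa = int(rng.integers(80, min(280, (budget - 27) // 3 - 1) + 1))
        label = "unannotated" if rng.random() < 0.5 else "viral-like"
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
        extras.append(
            _GenePlan(
                protein=_random_filler_protein(rng, n_aa),
                label=label,
                keywords={"hypothetical protein"} if label == "unannotated" else {"phage protein"},
                strand=strand,
            )
        )
        budget -= 3 * (n_aa + 1) + 27

    n_head = max(1 + n_amgs, (len(extras) + 1 + n_amgs) // 3)
    head_extras = extras[: max(0, n_head - 1 - n_amgs)]
    cassette_fill = extras[len(head_extras) : len(head_extras) + n_amgs + 1]
    tail = extras[len(head_extras) + len(cassette_fill) :]

    cassette: list[_GenePlan] = []
    for i, amg in enumerate(amg_plans):
        if i < len(cassette_fill):
            cassette.append(cassette_fill[i])
        cassette.append(amg)
    cassette.extend(cassette_fill[len(amg_plans) :])
    return [hallmark] + viral_like + head_extras + cassette + tail


def _plan_host_genes(
    rng: np.random.Generator,
    cfg: SimConfig,
    target_len: int,
    homologs: Sequence[tuple[str, str]],  # (family, phage protein)
    reserve_tail: int,
) -> list[_GenePlan]:
    plans: list[_GenePlan] = []
    for fam, phage_protein in homologs:
        plans.append(
            _GenePlan(
                protein=_mutate_protein(rng, phage_protein),
                label="microbial-like",
                keywords={f"{fam} sulfur metabolism"},
                family=fam,
            )
        )
    budget = target_len - reserve_tail - sum(
        3 * (len(p.protein) + 1) + 27 for p in plans
    )
    while budget > 3 * 81 + 27:
        n_aa = int(rng.integers(80, min(280, (budget - 27) // 3 - 1) + 1))
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
        plans.append(
            _GenePlan(
                protein=_random_filler_protein(rng, n_aa),
                label="microbial-like",
                keywords={"ABC transporter"},
                strand=strand,
            )
        )
        budget -= 3 * (n_aa + 1) + 27
    # keep the sulfur operon inside the fragment, not at its very edge
    rng.shuffle(plans)  # type: ignore[arg-type]
    return plans


# ---------------------------------------------------------------------------
# CRISPR planting
# ---------------------------------------------------------------------------

def plant_crispr_array(
    host_genome: str,
    target_phage: str,
    rng: np.random.Generator,
    repeat_len: int = 25,
    spacer_len: int = 32,
    n_spacers: int = 3,
    mismatches_per_spacer: int = 0,
    position: int | None = None,
) -> tuple[str, list[dict]]:
    """Insert a repeat-spacer array whose spacers are copied from a phage.

    The array is ``repeat + (spacer + repeat) * n``: ``n`` spacers flanked by
    ``n + 1`` identical repeat copies.  Each spacer is an exact (or
    ``mismatches_per_spacer``-substituted) copy of a random phage window.
    Returns the modified genome and per-spacer truth records (phage origin
    position, sequence as planted, mismatch count).
    """
    if n_spacers == 0:
        return host_genome, []
    if len(target_phage) < spacer_len:
        raise ValueError("target phage shorter than spacer length")
    repeat = "".join(_BASES[i] for i in rng.integers(0, 4, size=repeat_len))
    spacers: list[dict] = []
    parts = [repeat]
    for idx in range(n_spacers):
        origin = int(rng.integers(0, len(target_phage) - spacer_len + 1))
        spacer = list(target_phage[origin : origin + spacer_len])
        mm_sites = rng.choice(spacer_len, size=mismatches_per_spacer, replace=False)
        for site in mm_sites:
            alternatives = [b for b in _BASES if b != spacer[site]]
            spacer[site] = alternatives[rng.integers(3)]
        spacer_seq = "".join(spacer)
        spacers.append(
            {
                "spacer_index": idx,
                "sequence": spacer_seq,
                "origin": origin,
                "mismatches": int(mismatches_per_spacer),
            }
        )
        parts.extend([spacer_seq, repeat])
    array = "".join(parts)
    pos = len(host_genome) if position is None else position
    return host_genome[:pos] + array + host_genome[pos:], spacers


def _crispr_array_len(cfg: SimConfig) -> int:
    n = cfg.crispr_spacers_per_host
    return 0 if n == 0 else (n + 1) * cfg.crispr_repeat_len + n * cfg.crispr_spacer_len


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def simulate_community(config: SimConfig) -> Community:
    """Generate phage and host contigs with planted, recorded ground truth.

    Host sulfur-operon genes are created one per planted phage AMG (assigned
    round-robin across hosts), so every AMG family has equal phage and host
    gene counts and a 1:1 true phage-host pairing; this makes the virocell
    closed form ``vR/(vR+1)`` exact on noise-free coverage.
    """
    rng = stream_rng(config.seed, "community")
    crispr_rng = stream_rng(config.seed, "crispr")
    manifest = TruthManifest()
    for sid in config.sample_ids:
        manifest.samples[sid] = {
            "v": config.virocell_fraction,
            "R": config.replication_factor,
        }
    contigs: list[ContigRecord] = []
    genes: dict[str, list[GeneRecord]] = {}

    amg_records: list[tuple[str, str, str]] = []  # (gene_id, family, protein)

    for p in range(config.n_phages):
        cid = f"phage_{p + 1:04d}"
        target = int(rng.integers(config.phage_len_range[0], config.phage_len_range[1] + 1))
        plans = _plan_phage_genes(rng, config, target)
        seq, gene_list = _assemble_contig(cid, plans, rng, target)
        contigs.append(ContigRecord(cid, seq))
        genes[cid] = gene_list
        manifest.contig_roles[cid] = "phage"
        for plan, gene in zip(plans, gene_list):
            truth = GeneTruth(
                gene_id=gene.gene_id,
                contig_id=cid,
                role="phage",
                family=plan.family,
                planted_amg=plan.planted_amg,
                dsrc_class=plan.dsrc_class,
            )
            manifest.genes.append(truth)
            if plan.planted_amg:
                amg_records.append((gene.gene_id, plan.family, plan.protein))

    # round-robin host homolog assignment: one host gene per phage AMG
    host_homologs: list[list[tuple[str, str, str]]] = [
        [] for _ in range(max(config.n_hosts, 1))
    ]
    if config.n_hosts > 0:
        for i, rec in enumerate(amg_records):
            host_homologs[i % config.n_hosts].append(rec)

    for h in range(config.n_hosts):
        cid = f"host_{h + 1:04d}"
        reserve = _crispr_array_len(config) if config.n_phages > 0 else 0
        target = int(rng.integers(config.host_len_range[0], config.host_len_range[1] + 1))
        homolog_specs = [(fam, prot) for (_gid, fam, prot) in host_homologs[h]]
        needed = (
            sum(3 * (len(p) + 1) + 27 for _f, p in homolog_specs) + reserve + 500
        )
        target = max(target, needed)
        if target > config.host_len_range[1]:
            raise ValueError(
                f"{cid}: sulfur operon ({needed} bp) exceeds host_len_range; "
                "increase n_hosts or the host length ceiling"
            )
        plans = _plan_host_genes(rng, config, target, homolog_specs, reserve)
        seq, gene_list = _assemble_contig(cid, plans, rng, target, reserve_tail=reserve)
        if reserve:
            phage = contigs[h % config.n_phages]
            seq, spacer_truth = plant_crispr_array(
                seq,
                phage.sequence,
                crispr_rng,
                repeat_len=config.crispr_repeat_len,
                spacer_len=config.crispr_spacer_len,
                n_spacers=config.crispr_spacers_per_host,
                mismatches_per_spacer=config.crispr_mismatches,
            )
            for s in spacer_truth:
                manifest.spacer_links.append(
                    SpacerTruth(
                        host_id=cid,
                        phage_id=phage.id,
                        spacer_index=s["spacer_index"],
                        sequence=s["sequence"],
                        mismatches=s["mismatches"],
                    )
                )
        contigs.append(ContigRecord(cid, seq))
        genes[cid] = gene_list
        manifest.contig_roles[cid] = "host"

        remaining = list(host_homologs[h])
        for plan, gene in zip(plans, gene_list):
            truth = GeneTruth(
                gene_id=gene.gene_id,
                contig_id=cid,
                role="host",
                family=plan.family,
            )
            manifest.genes.append(truth)
            if plan.family is not None:
                # pair with the first unpaired phage AMG of this family
                for j, (pgid, fam, _prot) in enumerate(remaining):
                    if fam == plan.family:
                        manifest.pairs.append(
                            PairTruth(
                                phage_gene_id=pgid,
                                host_gene_id=gene.gene_id,
                                family=fam,
                            )
                        )
                        remaining.pop(j)
                        break

    return Community(contigs=contigs, genes=genes, manifest=manifest)


# ---------------------------------------------------------------------------
# Coverage and transcripts
# ---------------------------------------------------------------------------

def simulate_coverage(manifest: TruthManifest, config: SimConfig) -> pd.DataFrame:
    """Per-gene, per-sample read coverage under the virocell model.

    Columns: ``sample_id, gene_id, source, family, coverage``.  Host genes
    draw around ``c0``, phage genes around ``c0*v*R``, with multiplicative
    lognormal noise of sigma ``coverage_noise`` (0 gives exact expectations).
    Only sulfur-family genes (planted AMGs and host homologs) are emitted;
    they are the substrate of all ratio arithmetic.
    """
    rng = stream_rng(config.seed, "coverage")
    rows = []
    fam_genes = manifest.family_genes()
    for sid in config.sample_ids:
        v = manifest.samples[sid]["v"]
        big_r = manifest.samples[sid]["R"]
        for g in fam_genes:
            base = (
                config.coverage_baseline * v * big_r
                if g.role == "phage"
                else config.coverage_baseline
            )
            noise = (
                float(np.exp(rng.normal(0.0, config.coverage_noise)))
                if config.coverage_noise > 0
                else 1.0
            )
            rows.append(
                {
                    "sample_id": sid,
                    "gene_id": g.gene_id,
                    "source": g.role,
                    "family": g.family,
                    "coverage": base * noise,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "source", "family", "coverage"])


def simulate_transcripts(
    manifest: TruthManifest,
    config: SimConfig,
    gene_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Two-condition transcript counts for sulfur-family genes.

    Columns: ``condition, gene_id, source, family, count, gene_length_bp,
    library_size``.  Background counts are Poisson around the baseline;
    under the hydrothermal condition phage AMG counts scale by
    ``condition_fold``.  Library sizes model total mapped reads (dominated
    by the rest of the transcriptome, hence identical across conditions).
    """
    rng = stream_rng(config.seed, "transcripts")
    rows = []
    for g in manifest.family_genes():
        length = (gene_lengths or {}).get(g.gene_id, 1000)
        for condition in ("background", "hydrothermal"):
            mean = config.transcript_baseline
            if condition == "hydrothermal" and g.role == "phage" and g.planted_amg:
                mean *= config.condition_fold
            rows.append(
                {
                    "condition": condition,
                    "gene_id": g.gene_id,
                    "source": g.role,
                    "family": g.family,
                    "count": int(rng.poisson(mean)),
                    "gene_length_bp": length,
                    "library_size": config.library_size,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "gene_id",
            "source",
            "family",
            "count",
            "gene_length_bp",
            "library_size",
        ],
    )


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------

def evolve_codon_pair(
    ancestor_len_codons: int,
    omega: float,
    divergence: float,
    seed: int | np.random.Generator,
) -> tuple[str, str, float]:
    """Evolve two coding sequences from a random common ancestor.

    Point mutations are proposed uniformly (random codon, random position,
    random alternative base) and accepted with probability 1 when synonymous
    and ``omega`` when nonsynonymous; proposals creating stop codons are
    rejected outright.  Mutations alternate between the two lineages until
    ``round(divergence * L)`` substitutions have been accepted in total.
    Returns the two stop-free CDS strings and the omega used.
    """
    if omega < 0 or divergence < 0:
        raise ValueError("omega and divergence must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = ancestor_len_codons
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=length)]
    seqs = [list(codons), list(codons)]
    target = int(round(divergence * length))
    accepted = 0
    lineage = 0
    while accepted < target:
        seq = seqs[lineage]
        ci = int(rng.integers(length))
        bi = int(rng.integers(3))
        old_codon = seq[ci]
        alternatives = [b for b in _BASES if b != old_codon[bi]]
        new_base = alternatives[int(rng.integers(3))]
        new_codon = old_codon[:bi] + new_base + old_codon[bi + 1 :]
        if new_codon in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[new_codon] == CODON_TO_AA[old_codon]
        if synonymous or rng.random() < omega:
            seq[ci] = new_codon
            accepted += 1
            lineage = 1 - lineage
    return "".join(seqs[0]), "".join(seqs[1]), omega


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_community(
    community: Community,
    outdir: str | Path,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Emit the community as the pipeline's on-disk input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["contigs"] = write_fasta(community.contigs, outdir / "contigs.fna")
    all_genes = community.all_genes()
    paths["proteins"] = write_fasta(
        {g.gene_id: g.protein for g in all_genes}, outdir / "proteins.faa"
    )
    paths["cds"] = write_fasta(
        {g.gene_id: g.cds for g in all_genes}, outdir / "cds.ffn"
    )
    paths["gff"] = write_gff3(all_genes, outdir / "genes.gff")
    paths["gene_table"] = write_gene_table(all_genes, outdir / "genes.tsv")
    ann = outdir / "annotations.tsv"
    with open(ann, "w") as fh:
        fh.write("gene_id\tcontig_id\tannotation_label\tkeyword_terms\n")
        for g in all_genes:
            fh.write(
                f"{g.gene_id}\t{g.contig_id}\t{g.annotation_label}\t"
                f"{';'.join(sorted(g.keyword_terms))}\n"
            )
    paths["annotations"] = ann
    truth = outdir / "truth.json"
    truth.write_text(community.manifest.to_json())
    paths["truth"] = truth
    if config is not None:
        coverage = simulate_coverage(community.manifest, config)
        coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
        paths["coverage"] = outdir / "coverage.tsv"
        lengths = {g.gene_id: g.end - g.start + 1 for g in all_genes}
        counts = simulate_transcripts(community.manifest, config, lengths)
        counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        paths["counts"] = outdir / "counts.tsv"
    return paths
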