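# Methods and design notes

This note documents the models behind `amgkit`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Conserved-residue motif validation

Each AMG family ships a fixed motif catalog (`data/motif_catalog.tsv`):

| family | motifs |
|---|---|
| DsrA | substrate binding `R`, `KxKxK`, `R`, `HeR`; siroheme binding `CxgxxxC`, `CxxdC` |
| DsrC | conserved two-cysteine motif, spelled `CxxxgxpxpxxC` and `CxxxxxxxxxxC` |
| SoxYZ | substrate-binding `ggCs`; variable `CC` |
| SoxC | cofactor/active sites `XxH`, `D`, `R`, `XxK` |
| SoxD | cytochrome c `CxxCHG`, `CMxxC` |

Uppercase letters are strictly required residues, lowercase letters are
partially conserved (needed for a *full* match, not a *strict* match), and
`x`/`X` match anything. The two DsrC spellings both span 12 residues with
cysteines at offsets 0 and 11; they are alternate descriptions of one
physical window (the spellings differ only in which interior positions are
marked partially conserved), so the catalog treats them as a shared window
and reports which spelling matched.

**Anchored mode** (default) globally aligns the query to an annotated
family reference (BLOSUM62, gap open 11, extend 1) and reads residues at
the mapped motif columns. This mirrors how conserved residues are checked
by eye in an alignment viewer and makes single-residue motifs (SoxC `D`,
`R`) meaningful. **Scan mode** searches motifs of length ≥ 2 directly, in
catalog order and non-overlapping — a fallback when no reference is
trusted. Ordering and non-overlap are enforced because the motifs occur in
a fixed order along the reference proteins; without the constraint,
rearranged spurious matches would pass.

The family references are synthetic template proteins: motif windows
embedded in a filler alphabet (`ALVTSNQIFWY`) chosen to contain none of the
strictly required motif residues, so a template's only strict matches are
its planted windows. They are labelled synthetic; they stand in for curated
reference alignments, which are not shipped.

DsrC/TusE classification reads the two conserved cysteines at
alignment-mapped columns: both present → functional DsrC; second only /
first only / neither → counted TusE-like (the tRNA-thiolation homolog that
lacks the full sulfur-carrier motif). In scan mode a lone cysteine cannot
be assigned to "first" vs "second" without a reference, so anchored mode is
the classification default.

## Viral-context heuristics

The phage verdict requires ≥ 1 viral hallmark gene AND (viral-like
annotations ≥ microbial-like, OR unannotated fraction ≥ 0.5); `not_phage`
requires 0 hallmarks and a microbial-like majority; anything else is
ambiguous. The 0.5 unannotated cutoff and the 0.7 microbial-density cutoff
in the contamination flag are package defaults exposed as parameters — the
underlying qualitative rules ("high proportion", "high density") have no
published numeric values. Contamination additionally requires an integrase
keyword somewhere on the contig (both conditions, not either). Lysogeny
keywords: integrase, recombination, repressor, prophage (case-insensitive
substring). Contigs under 5 kb are rejected before screening; AMG
neighborhoods are the 11 proteins centered on the AMG and are rejected
outright when fewer than 5 genes flank either side, because truncated
windows are not comparable across contigs.

## Taxonomy voting

Each protein contributes its best hit (highest bitscore). At each rank the
taxon maximizing *summed* bitscore wins — operationalizing "most likely
rather than most common"; a taxon hit by few proteins at high scores can
out-vote a more common low-score taxon. Ties break by higher mean bitscore,
then lexicographically. Lower ranks are elected only among hits carrying
the winning higher rank, so calls are hierarchically consistent by
construction. A rank whose winner is supported by fewer than `min_support`
(default 0.10) of the contig's proteins is reported unknown. The weighting
rule and threshold are this package's own concrete interpretation of a
procedure whose internals are not published; both are configurable.

Reference dereplication uses greedy longest-first k-mer containment
(k = 15): a sequence is absorbed when the fraction of its distinct k-mers
found in a representative reaches `coverage × identity^k` — the expected
k-mer survival when the coverage fraction of the shorter sequence aligns at
the threshold per-base identity (0.90 × 0.95¹⁵ ≈ 0.417 at the defaults).

## Protein grouping

Greedy centroid clustering emulates an external clustering tool at its
printed thresholds: input ordered by (length descending, id ascending);
each sequence joins the first centroid with identity ≥ 0.30 and coverage
≥ 0.60 **of both sequences** (the coverage mode is stated explicitly here
because only `-c 0.6` is printed), else founds a cluster. A shared-4-mer
screen skips hopeless alignments. Identity is identical residues over
alignment columns excluding terminal gaps; alignment arguments are
canonicalized by (length, lexicographic) order because co-optimal
alignments are not unique and symmetry of identity is a contract.

Two retention modes exist because the main analysis keeps groups spanning
≥ 2 distinct genomes while the randomized validation keeps groups with
≥ 2 members. `grouping_stats` reports retained clusters per protein
(3 decimals); `subsample_validation` repeats sampling-without-replacement
clustering (default 94 genomes × 100 iterations) and summarizes.

## NG86 dN/dS

Synonymous sites per codon are the fractions of the nine single-base
neighbors that preserve the amino acid; stop-creating changes count as
nonsynonymous sites, so S + N = 3L holds exactly. Site totals are averaged
over the two sequences. Differences are averaged with equal weight over
all substitution orders between two codons, excluding pathways through stop
codons; in the (never observed for ≤ 2 differences) case that all orders
cross a stop, unrestricted pathways are used as a fallback rather than
dropping the codon. Proportions are Jukes–Cantor corrected; p ≥ 3/4 yields
an explicit saturation sentinel and dS = 0 an explicit undefined sentinel —
sentinels are excluded from family means with the exclusion count reported,
never silently dropped. Ratios are computed pairwise over all unordered
pairs (whether the original analysis was pairwise or reference-anchored is
not stated; pairwise is implemented and labelled as such). Equal pathway
weighting was chosen because it is the assumption-free baseline; the
codon-evolution generator uses uniform base proposals for the same reason,
keeping recovery unbiased.

## Virocell abundance model

Let `v` be the fraction of cells in a virocell state and `R` the phage:host
per-gene coverage amplification inside a virocell. Every cell contributes
one coverage unit per host gene; virocells contribute `R` units per phage
gene. The community phage:total gene-coverage ratio for a family with equal
phage and host gene counts is then `vR/(vR+1)`. Given an observed
within-pair ratio `r`, the implied amplification is `R = r/(1-r)` and the
expected community ratio `vR/(vR+1)`; at `v = 1` this returns `r` exactly.
The literal product `v·r` is also available behind a flag, but it
understates the expectation because it ignores that only infected cells
carry phage genes; at a marine virocell fraction of 16% and within-pair
ratios near 93% the two readings give 68% vs 15%.

One consequence the tests make explicit: under this generator the
within-pair ratio *equals* the community ratio (the paired host gene draws
coverage from all cells), so recovering `r = R/(R+1)` from pair ratios is
exact only at `v = 1`. In real data the paired host is a specific
population whose infected fraction can far exceed the community average,
which is how within-pair ratios above 50% coexist with community ratios
near 30%.

Expression is RPKM (`count / (library_size/10⁶) / (length/10³)`);
condition ratios return +∞ when the denominator is zero with a positive
numerator and an undefined sentinel for 0/0, both excluded from means with
counts reported. Energy budgets multiply total available energy, the
pathway fraction and the phage coverage ratio; the headline value is
rounded to 2 significant figures (raw value retained).

## CRISPR linkage

Repeat detection requires **exact** tandem repeat copies (19–38 bp,
≥ 3 copies) separated by 19–48 bp spacers; fuzzy repeats are out of scope
because exactness gives a brute-force-checkable contract and suffices for
ground-truth recovery. Overlapping candidate arrays (shifted or truncated
re-detections of one repeat) are resolved by preferring more copies, then
longer repeats, then earlier starts — copy count first, because a chance
boundary-base coincidence can otherwise promote a shifted variant with
fewer copies. Spacer matching is Hamming-only (no indels, implied by the
100%-coverage 0–2-mismatch hit rule), both strands by default with a flag
to disable. The ≥ 10 kb host-length filter is applied by the CLI driver and
is configurable.

## Synthetic community generator

The generator's defaults are the study conditions: phage contigs
5–40 kb carrying 1–4 AMGs, host fragments 10–60 kb, AMG family weights
(DsrA 0.17, DsrC 0.62, SoxYZ 0.19, SoxC 0.01, SoxD 0.01) matching the
observed family census of 227 AMGs, virocell fraction 0.16 (marine
average), condition fold 15 (hydrothermal:background expression), ω = 0.2
and divergence 0.2 for codon evolution. The replication factor default
R = 10 (within-pair ratio ≈ 0.91) reflects within-pair ratios well above
50%; coverage dispersion (lognormal σ = 0.3) has no published empirical
value and is configurable. The transcript library size (10⁶) models total
mapped reads dominated by the rest of the transcriptome, which is why both
condition libraries are equal — AMG reads are a negligible fraction.

Phage contigs place one hallmark gene and viral-like structural genes ahead
of an auxiliary cassette containing the AMGs (labelled microbial-like, as
annotation pipelines would) interleaved with unannotated genes. Host
sulfur-operon genes are created one per planted phage AMG (round-robin
across hosts, lightly mutated copies of the AMG protein), which makes
phage and host gene counts equal per family — the condition under which
the `vR/(vR+1)` closed form is exact — and yields a 1:1 true pairing.
Genes are planted ATG→stop with stop-rich `TAA`-repeat spacers so the
naive ORF finder (ATG-only starts, table 11, both strands) recovers
≥ 95% of them exactly. Non-motif protein positions draw from the filler
alphabet so planted motif windows remain each protein's only strict
matches. All randomness derives from one master seed through numbered
`SeedSequence` streams (community 0, coverage 1, transcripts 2, codons 3,
CRISPR 4), so regenerating one table never perturbs another and all
outputs are byte-identical per seed.

What the generator does **not** emulate: read-level sequencing error,
assembly artifacts, genome completeness tiers, strain microdiversity,
compositional (GC/codon) realism, or hosts infected by AMG-free phages.
Passing tests therefore demonstrate correctness of the pipeline's logic
and arithmetic under the stated model, not robustness to the full
messiness of environmental metagenomes — in particular, real within-pair
ratios reflect population structure the generator deliberately omits.

## Problem sizes

The test suite and the acceptance script run at desk scale as a design
choice: communities of ~4–25 phages and 2–5 hosts, 1,000-trial brute-force
equivalence checks for the motif scanner and spacer matcher, the full
61×61 sense-codon oracle comparison, and 50×500-codon selection
simulations. These sizes give stable statistics (e.g. mean dN/dS standard
error ≈ 0.005 at ω = 0.2) while keeping the whole suite under a minute.

## Known limitations

* Anchored motif checking depends on a sensible global alignment; for
  proteins unrelated to the family reference the mapped columns are
  arbitrary (the verdict is then correctly negative, but positions are
  meaningless).
* The greedy clusterer is order-deterministic but, like the tool it
  emulates, not a global optimum; permuting input yields identical
  clusters only because the canonical ordering is applied internally.
* `evolve_codon_pair` controls the *realized* substitution count, not a
  Poisson-distributed expectation, trading a little realism for exact
  divergence control.
* Taxonomy voting has no notion of reference database bias; support
  fractions measure agreement among hits, not database completeness.
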