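# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the problem was genuinely open.

## Pattern engine

Patterns are ordered lists of position elements over the 20-letter amino
acid alphabet: exact residues, residue classes, and wildcards. The syntax
extends classical PROSITE notation with the hydrophobic class Φ, usable
bare or inside brackets (where it unions with the listed residues). `(n)`
repeats are accepted after any element — this is needed for the older
Walker B consensus `[Φ](4)-[D]` — and variable-length repeats `(n,m)` are
rejected, so every pattern has a fixed span and overlapping matches are
well defined. All matches are reported; deduplication is a downstream
concern.

Φ defaults to {A, C, F, I, L, M, V, W}, the classical strongly hydrophobic
residues. There is no single agreed hydrophobic set, so the choice is a
configurable parameter of `parse_pattern`, not an assertion of truth.
Non-standard letters (B, Z, X, …) never satisfy a class or exact element;
a policy flag decides whether scanning rejects such sequences outright or
lets wildcards optionally accept them (`never-match` +
`wildcard_matches_unknown`). The default rejects, which is the
conservative identification behaviour.

## NBD scanner

An NBD is accepted only as a complete Walker A → C-loop → Walker B
triplet. The spacing windows (C-loop start 30–200 residues after Walker A
end; Walker B start 5–80 residues after C-loop end) are not dictated by
the motif definitions; they reflect typical ABC NBD geometry — the
signature motif sits on a separate subdomain from the Walker A
P-loop, and Walker B follows closely — and keep accidental assemblies
rare. Assembly is greedy left-to-right with earliest-compatible pairing,
which is deterministic and matches how one reads an alignment figure;
incomplete triplets (e.g. a missing Walker B within the window) are
dropped rather than patched.

Class assignment reads residues at diagnostic positions (defaults:
Walker A position 8; C-loop positions 6, 8 and 12) and looks the
concatenated string up in an editable table, falling back to the
Hamming-nearest exemplar with ties mapped to `unassigned`. The published
description of which alignment columns discriminate the classes uses
alignment coordinates that partly fall outside the fixed motif spans, and
the residue-to-class mapping itself is not published; the shipped table is
therefore an explicit heuristic (Class1 ≈ Protein White/Rim protein,
Class2 ≈ Uup, Class3 ≈ efflux families) that users can replace.

## Consensus derivation and information content

Fixed-span motif extraction yields pre-aligned blocks, so no multiple
sequence alignment is needed. Per column with observed residue set S:

* |S| = 1 → exact element;
* otherwise, if at most `class_threshold` (default 10) residues reach
  frequency `freq_floor` (default 0.05) and S is not the whole alphabet →
  bracket class over **all** of S;
* otherwise → wildcard.

Classes keep every observed residue — rare residues stop counting toward
the class-size test but are never dropped — so a derived pattern matches
100% of its source rows by construction. This round-trip guarantee was
chosen over the alternative (dropping sub-floor residues) because a
consensus that fails on its own training rows is not useful as a scanning
pattern. The defaults reproduce bracket sizes of the same order as the
shipped generalized motifs (e.g. a 9-residue class at the third signature
position). Raising `class_threshold` converts wildcard columns into
explicit classes and never alters exact/class columns.

Information content is IC = log2(20) − H(p) bits per column, with an
optional uniform pseudocount; the default pseudocount is 0, i.e. no
small-sample correction, which keeps the degenerate cases exact (single
residue → log2 20 ≈ 4.32 bits; uniform → 0). Logo rendering is out of
scope; only the numbers are produced.

## Domain architecture

The rule set stores the arrangement strings of the six structural types
verbatim (A-B-A-B → 1; B-C-B/B-E-B → 3; B-C-B-C/B-C → 4; B-B/B-B-B → 5;
B-D-B/B-B-D-B → 6) and resolves the one ambiguous string, A-B, to type 2
unless the record carries ATM1 family membership plus a full-transporter
evidence flag, in which case it is type 1. This keeps classification
deterministic while representing both published uses of A-B. Unknown
arrangements return `unclassified` rather than raising. Family labels are
consumed as input metadata; this module never infers family from
sequence. Cohort summaries bin introns as 0/1/2/3/4+ — the published
marginals list "more than 4" next to bins 0–3 that already sum to the
cohort, so a 4-intron gene would be unaccounted either way; 4+ is the
self-consistent reading.

## Promoter census

IUPAC consensi compile to overlap-counting matchers (regex lookahead).
Occurrences are counted individually even when overlapping; with
`both_strands` on, the reverse-complement strand is scanned too, so a
palindromic consensus counts once per strand at the same position — this
is documented behaviour, since the reference web tool's convention is
unspecified. A sequence `N` matches only a consensus `N`. Promoters longer
than the configured 1000 bp are truncated 3′-anchored (keeping the
gene-proximal end) with a warning.

The shipped 39-entry dictionary is an editable set of yeast-style consensi
with the eight stress-response regulators (GCR1, GCN4, ADR1, STRE, HSTF,
PHO4, GC/FAR, ABF1) flagged. The consensus strings themselves are external
defaults, chosen at ≥10 bits of specificity; the census machinery treats
them purely as data. Per-family summaries report arithmetic means rounded
to integers, the customary display precision for such tables.

## Expression screen

RPKM uses the supplied per-sample mapped-read totals N rather than column
sums of the count matrix — which denominator a given alignment pipeline
used is an upstream decision, so N is an explicit input. The log
transform defaults to log2(RPKM + 1): real count data contain zeros, so a
pure log2 is undefined there; the offset is a parameter for users who want
the literal transform on strictly positive matrices.

Clustering delegates to scipy's agglomerative implementation with
Euclidean distance and complete linkage; merge heights are the maximum
inter-cluster pairwise distance and are non-decreasing. The test suite
checks it step-by-step against an independent brute-force O(n³)
agglomerative loop on random instances (ties are measure-zero there; on
tied data scipy's internal order decides).

"Highly expressed" has no published threshold; the default rule flags a
gene whose RPKM reaches the top quartile of its condition, and an absolute
threshold rule is available. The synthetic count generator's ledger uses
the absolute rule (RPKM ≥ 100) because its high/low design is built around
that margin. Replicate columns, if present, are averaged before
clustering.

## qPCR (2^−ΔΔCt)

ΔCt subtracts the arithmetic mean Ct of the reference genes within the
same well set (condition × timepoint × replicate); arithmetic mean of Ct
equals geometric mean of quantities, the standard multi-reference
combination. The calibrator defaults to the same condition's 0-h sample,
so control and treatment form separate time series and the differential
response is their log2 difference, matching stress-course designs; a
control-at-same-time calibrator can be passed explicitly. Fold at the
calibrator is exactly 1 (the mean is computed as a difference of means,
not through per-replicate rounding).

Control-vs-treatment significance is an independent-samples t-test
(pooled variance by default, Welch optional) on per-replicate ΔCt values
at the same timepoint. Calibrator subtraction is deliberately excluded
from the test: it adds the same random constant to every replicate of a
series, which would correlate observations and inflate the type-I error.
With it excluded, the null calibration is exact (≈5% of null runs
significant at α = 0.05, verified by simulation). Zero-variance
degenerate groups follow the convention t = 0, p = 1 for equal means.
Stars map p < 0.05 → * and p < 0.01 → **. Amplification-efficiency
correction is out of scope.

## Protein properties and gene models

Molecular weight sums average residue masses plus one water. The pI is
the root of the Henderson–Hasselbalch net-charge function, found by
bisection on [0, 14] to 1e-4 pH; the function is strictly decreasing in
pH, so convergence is unconditional. Two editable pKa sets ship
("expasy"-style Bjellqvist values by default, EMBOSS as an alternative) —
published pI ranges depend on the table used, so it is a parameter.
Boundary classification: pI > 7 basic, < 7 acidic, exactly 7 neutral
(flagged). Intron counts come from GFF3 exon lines (1-based inclusive
coordinates) of the canonical transcript, taken as the transcript with
the largest summed exon length; introns = exons − 1.

## Synthetic data: what it emulates, and what it does not

The generators are parameterized to the study-scale cohort: 44 genes in
nine families (ATM1 4, CFTR 6, MdlB 5, MDR 8, MRP 9, Protein White 4, Rim
protein 2, Uup 5, 3a0123 1); structural types 1–6 with counts
27/6/2/4/2/3 (types 1–2 = 75%); intron bins 5/5/13/4/17 spanning 0–15; pI
in [5.48, 9.87] split 27 acidic / 17 basic; MW in [55.33, 187.56] kDa; 79
NBDs (one per B domain of each arrangement); a promoter census of 794
sites, 39 types, 541 stress-flagged, per-gene totals 9–32 with family
means 21 (ATM1, most) down to 13 (Rim protein, fewest) and Uup the most
diverse in motif kinds; two pinned marker genes whose RPKM values
(ABC31: 8537 MM / 59214 PdPap; ABC42: 3957 MM / 11790 N-hungry) are exact
by construction at L = 1000 bp and N = 10⁶ mapped reads; 17 of 39
transport and 4 of 5 translation-regulating genes highly expressed in at
least one condition; and Ct tables over 2 conditions × 4 timepoints × 3
replicates with planted −ΔΔCt trajectories peaking at the magnitudes
3.13, 2.54, 4.92, 5.09 and −1.83. Where a quantity is only partially
published (the per-protein type-1/2 split within ATM1 and MdlB, the two
unprinted conditions of each marker gene, the non-peak qPCR timepoints),
the generator fixes one consistent synthetic choice and labels it as
such in its ledger.

Protein and promoter backgrounds are i.i.d. uniform; accidental motif
occurrences are mutated away by a screening pass (on by default) so that
planted-truth tests are exact — the ledger, never the output, is the
source of truth in tests. Consequently the synthetic data do **not**
emulate residue composition bias, GC content, motif clustering in real
promoters, dispersion structure across genes, or genuine biological
variation between NBD copies beyond the planted class diagnostics.
Passing tests therefore demonstrate correctness of the algorithms under
known truth, not recovery performance on real genomes. Read-level
simulation (FASTQ) and genome assembly are out of scope.

Negative-binomial counts use dispersion r = 50 (CV ≈ 14% at high means),
enough noise to be non-trivial but far from the high/low decision margin;
sampled cells are re-drawn if they cross their designed side of the
RPKM = 100 threshold, keeping the ledgered flags exact. Ct noise is 0.2
cycles per well, a typical technical-replicate SD.

All randomness flows through `numpy.random.default_rng` seeded from the
user seed plus a per-generator offset; fixed seeds give byte-identical
FASTA/tables across platforms (Ct values are rounded to 3 decimals when
written, the only float-formatting step).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full 44-gene cohort
for every planted-truth check, 1000 random 200-mers against all six
shipped patterns for the regex-oracle comparison, 100 random 8-gene
instances against the brute-force clustering oracle, and 500 simulated
experiments per planted qPCR effect (with 60 replicate experiments
averaged for the reported recoveries). These sizes give sub-minute wall
times while keeping Monte-Carlo standard errors an order of magnitude
below the tolerances they are checked against.

## Known limitations

* Families and TMD annotations are inputs; nothing here predicts domain
  content from sequence (no HMMs, no transmembrane prediction).
* The NBD class table and the promoter motif dictionary are heuristics /
  external defaults, shipped to be edited.
* Variable-length pattern repeats are unsupported (none of the shipped
  motifs need them).
* Phylogenetics and 3D structure prediction are explicitly out of scope;
  structural types are assigned from arrangements, not structures.
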