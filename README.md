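# abcfam

A toolkit for characterizing ATP-binding cassette (ABC) transporter gene
families in fungal genomes, built around the kind of cohort survey used for
biocontrol fungi such as *Trichoderma*: motif-level detection of
nucleotide-binding domains (NBDs), structural typing from conserved-domain
arrangements, a promoter cis-element census, an RPKM expression screen, and
2^−ΔΔCt RT-qPCR quantification of toxin-stress responses.

It is aimed at comparative genomicists and molecular mycologists who need
each of these steps as a reusable, tested library function (or shell
command) rather than a chain of web servers.

## What it computes

**NBD motif detection.** ABC-ATPase domains are located as ordered motif
triplets — Walker A `G-XX-[GA]-X-G-K-[ST]`, the ABC signature (C-loop)
`[LIVMFYC]-S-[SGQDEVAHL]-G-X(3)-[RKALV]-[LIVMYATC]-X-[LIVMF]-[AGCT]`, and
Walker B `[ΦHY]-[ΦCY]-[ΦC]-[ΦCT]-[D]-[DEI]` (Φ = hydrophobic residue) —
matched by an extended PROSITE-style pattern engine and assembled under
spacing constraints. Detected NBDs are indexed by chain position and
assigned sequence classes from diagnostic residues.

**Domain-arrangement typing.** Arrangement strings over the domain alphabet
A–E (ABC-membrane, ABC-ATPase, ABC2-membrane, ABC-tran-2, acyl-transfer-3)
map deterministically to six structural types; types 1–4 are transmembrane
transporters, 5–6 regulate translation.

**Promoter census.** Named IUPAC consensus motifs are counted (overlaps
included, optionally both strands) in 1000-bp upstream regions, with
stress-response and per-family rollups.

**Expression screen.** RPKM = C·10⁹/(N·L); log2 transform; gene clustering
by Euclidean distance with complete linkage; per-condition high-expression
flags.

**qPCR.** ΔCt against the mean of multiple reference genes, ΔΔCt against a
0-h calibrator, fold = 2^−ΔΔCt, and independent-samples t-tests with
significance stars.

A seeded synthetic-data module (`abcfam.simulate`) generates every input —
proteins with planted NBD triplets, promoters with planted sites, count
matrices, Ct tables, and a 44-gene cohort registry — together with
ground-truth ledgers, so the whole pipeline is testable offline.

## Worked example

```python
from abcfam import simulate, architecture, nbd, consensus, promoter, expression, qpcr

registry = simulate.gen_cohort_registry(seed=1)
s = architecture.cohort_summary(registry.records)
print("genes:", s["total"], "| types 1+2:", s["pct_types_1_2"], "%")

proteins = simulate.gen_proteins(registry=registry, seed=1)
pats = nbd.nbd_patterns()
hits = {pid: nbd.find_nbds(seq, pats) for pid, seq in proteins.sequences.items()}
print("NBDs:", sum(len(h) for h in hits.values()))

block = nbd.extract_motif_block(hits, "walker_a")
print("derived Walker A consensus:", consensus.derive_consensus(block).source_text)

promoters = simulate.gen_promoters(registry=registry, seed=1)
table = promoter.census(promoters.sequences, promoters.dictionary)
print("promoter motifs:", table.grand_total, "| types:", table.distinct_types_cohort,
      "| stress:", table.stress_total)

expr = expression.rpkm(simulate.gen_counts(registry=registry, seed=1).matrix)
print("ABC31 RPKM:", expr.loc["ABC31"].round(0).to_dict())

ct = simulate.gen_ct(seed=1)
r = qpcr.fold_change(ct.table, "ABC31", "treatment", 6.0)
print(f"ABC31 toxin response at 6 h: fold {r.fold:.1f} (log2 {r.log2_fold_change:.2f}), p = {r.p_value:.2g}")
```

prints

```
genes: 44 | types 1+2: 75.0 %
NBDs: 79
derived Walker A consensus: G-X(2)-[AG]-[ACDEFGHIKLMNPRSTVWY]-G-K-[ST]
promoter motifs: 794 | types: 39 | stress: 541
ABC31 RPKM: {'MM': 8537.0, 'C-hungry': 21000.0, 'N-hungry': 32000.0, 'PdPap': 59214.0}
ABC31 toxin response at 6 h: fold 35.4 (log2 5.15), p = 2.3e-05
```

Of the 44-gene cohort, 75% are full or half transporters of structural
types 1–2; the 79 detected NBDs regenerate a Walker A consensus matching
the shipped generalized motif; the promoter census finds 794 sites of 39
motif types, 541 of them on stress-response elements; the Uup-family gene
ABC31 is the most expressed gene in every condition (peaking at 59214 RPKM
on plant-material medium) and is induced ~2^5.1-fold 6 h after toxin
exposure.

The same steps are available from the shell:

```sh
abcfam simulate --seed 1 --outdir sim/
abcfam scan-nbd --fasta sim/proteins.fa --out nbds.tsv
abcfam census --promoters sim/promoters.fa --out census.tsv
abcfam ddct --ct sim/ct.csv --refs actin,alpha-tubulin,beta-tubulin --out folds.tsv
```

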