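# circrbp

Downstream analysis of circular RNA (circRNA) and RNA-binding-protein
(RBP) expression in tumor cohorts — the part of a circRNA study that
starts once backsplice junctions have been detected and reads counted.

Glioblastoma and other tumors show broad circRNA downregulation alongside
deregulation of roughly half the known RBPome, and the two are coupled:
RBPs bind flanking introns to promote back-splicing, and mature circles
can in turn sequester RBPs.  `circrbp` packages the analyses used to
dissect that interplay:

- **Expression** — TMM normalization, common-dispersion negative-binomial
  exact tests for differential circRNA/gene expression (BH FDR), RBP-list
  filtering, Spearman RBP–circRNA correlation, and the circular-to-linear
  ratio CLR = circ/(circ + lin), where CLR > 0.5 means the circle
  outnumbers its linear host transcript.
- **Sequence regions** — strand-aware extraction of circRNA bodies,
  1000-nt flanking windows, and 100-nt backsplice-junction boundary
  windows (50 nt intron side + 50 nt circRNA side).
- **Motif inference** — 6-mer enrichment between DE and non-DE circRNA
  sequence sets (two-sided Fisher exact per k-mer), attribution of
  enriched 6-mers to RBP position probability matrices (hypergeometric
  over-representation over the 4^6 k-mer universe), region-resolved motif
  frequency profiles, and the dual-role intersection of body- and
  flank-enriched RBPs.
- **Stratification** — signature-based molecular subtype assignment, then
  RBP-driven regrouping: 1-D 2-means discretizability, a chi-square
  subtype-independence filter, silhouette-selected k-means, and one-way
  ANOVA discriminant RBPs.
- **Survival** — expression-quartile grouping (Q1 low / Q4 high), a
  from-first-principles Kaplan-Meier estimator and Mantel-Haenszel
  log-rank test, and a per-RBP low-vs-high survival screen.
- **Synthetic data** — a fully specified generator (genome, circRNAs,
  planted hexamer motifs, NB counts, clusters, subtypes, survival) with
  recorded ground truth, so every stage has a recovery test.

See `docs/methods.md` for the statistical details and design rationale.

## Worked example

`examples/` contains one narrative script per capability.  The motif
inference example plants TTTTTT at 6 copies/kb into the bodies of
downregulated circRNAs (0.5/kb elsewhere) and asks the pipeline to find
it:

```bash
$ python examples/03_motif_enrichment.py
top enriched 6-mers in down-DE circRNA bodies (vs non-DE):
  TTTTTT  log2 enrichment +3.34  FDR 0.00e+00
  TTTTTG  log2 enrichment +2.57  FDR 1.12e-120
  GTTTTT  log2 enrichment +2.55  FDR 7.21e-123
  TTTTTA  log2 enrichment +2.51  FDR 2.20e-120
  CTTTTT  log2 enrichment +2.51  FDR 6.13e-121

RBP motif attribution (hypergeometric over the 6-mer universe):
  RBP_URICH    p=1.07e-02  FDR=4.30e-02  [significant]
  RBP_GCRICH   p=1.00e+00  FDR=1.00e+00  [ns]
  RBP_CTRL1    p=1.00e+00  FDR=1.00e+00  [ns]
  RBP_CTRL2    p=1.00e+00  FDR=1.00e+00  [ns]
```

The planted hexamer tops the 6-mer table (its one-base neighbours rise
with it, as overlapping windows must), and only the PWM built on the
planted U-rich motif is significant — the G/C-rich and control PWMs are
not.  On real data the same call sequence takes your own FASTA/BED/TSV
inputs in place of the generator.

The end-to-end pipeline runs over a directory of plain files, stage by
stage or in one go, from Python:

```python
from circrbp.pipeline import run_demo
manifest = run_demo("rundir", seed=42)   # generate synthetic data + all stages
```

or from the shell:

```bash
circrbp generate --outdir rundir --seed 42
circrbp run-all --outdir rundir --seed 42   # writes manifest.json + stage TSVs
```

Stage outputs (`de_circ.tsv`, `clr.tsv`, `kmer_enrichment_*.tsv`,
`motif_enrichment_*.tsv`, `motif_profiles.tsv`, `stratification_*.tsv`,
`survival_screen.tsv`, ...) are plain TSVs, so any stage can be fed files
produced elsewhere.

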