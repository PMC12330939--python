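"""k-mer enrichment and RBP motif attribution on planted sequences.

Plants TTTTTT at 6 copies/kb into downregulated circRNA bodies (0.5/kb
elsewhere), runs the 6-mer Fisher enrichment of down-DE vs non-DE bodies,
and maps enriched 6-mers onto a small PWM library by hypergeometric
over-representation.
"""

from circrbp.motifs import kmer_enrichment, motif_enrichment_from_kmers
from circrbp.regions import extract_body
from circrbp.synthetic import (SynthParams, SyntheticTruth, assign_de_status,
                               default_pwm_library, generate_circ_annotations,
                               generate_genome, plant_motifs)

params = SynthParams(chrom_len=4_000_000, n_circ=1000,
                     circ_len_min=1000, circ_len_max=1000, seed=3)
genome = generate_genome(params)
circs = generate_circ_annotations(genome, params)
truth = SyntheticTruth(de_status=assign_de_status(circs, params))
genome = plant_motifs(genome, circs, truth, params)

bodies = {c.circ_id: extract_body(c, genome).sequence for c in circs}
fg = [bodies[c] for c, s in truth.de_status.items() if s == "down"]
bg = [bodies[c] for c, s in truth.de_status.items() if s == "null"]

table = kmer_enrichment(fg, bg, k=6, motif_fdr=0.1)
top = table[table["enriched"]].nlargest(5, "log2_enrichment")
print("top enriched 6-mers in down-DE circRNA bodies (vs non-DE):")
for _, row in top.iterrows():
    print(f"  {row['kmer']}  log2 enrichment {row['log2_enrichment']:+.2f}  FDR {row['fdr']:.2e}")

res = motif_enrichment_from_kmers(table, default_pwm_library(params))
print("\nRBP motif attribution (hypergeometric over the 6-mer universe):")
for _, row in res.iterrows():
    mark = "significant" if row["significant"] else "ns"
    print(f"  {row['rbp_name']:<12} p={row['pvalue']:.2e}  FDR={row['fdr']:.2e}  [{mark}]")
print("\nThe U-rich PWM should be the only significant hit: its hexamer was "
      "planted preferentially in the downregulated set.")
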