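"""Gene-structure metrics from a BED12 model: the eight length parameters.

For multi-transcript genes the longest spliced transcript is the
representative; UTR lengths are genomic distances between the transcription
boundary and the coding boundary on the strand-appropriate side.
"""

import io

from promdiver import parse_gene_models, select_representative, structure_metrics

BED12 = (
    "chr1\t1000\t2000\tG1|G1.t1\t0\t+\t1100\t1900\t0\t2\t200,200,\t0,800,\n"
    "chr1\t1000\t1200\tG1|G1.t2\t0\t+\t1100\t1200\t0\t1\t200,\t0,\n"
)

genes = parse_gene_models(io.StringIO(BED12))
best = select_representative(genes["G1"])
m = structure_metrics(best)
print(f"representative transcript : {best.tx_id}")
print(f"genomic length            : {m.genomic_len}")
print(f"total exon / total intron : {m.exon_total_len} / {m.intron_total_len}")
print(f"exons / introns           : {m.n_exon} / {m.n_intron}")
print(f"CDS (spliced)             : {m.cds_len}")
print(f"5' UTR / 3' UTR           : {m.utr5_len} / {m.utr3_len}")
# t1 (400 spliced bases) beats t2 (200); its two 200-bp exons flank a 600-bp
# intron, the CDS spans 1100-1900 leaving 100-bp UTRs on each side, and
# genomic length = exon total + intron total holds by construction.
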