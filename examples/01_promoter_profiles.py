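"""Promoter profiling: cluster TSS evidence into promoters and classify genes.

TSSs within 500 bp of each other (single-linkage chaining) belong to one
promoter; the promoter count bins each gene into SP / AP2 / AP3_4 / AP5plus.
"""

import io

from promdiver import parse_tss_table, promoter_profile

BED6 = """\
# chrom  start  end  gene  support  strand
chr1\t1000\t1001\tGNAS-like\t12\t+
chr1\t1200\t1201\tGNAS-like\t4\t+
chr1\t2500\t2501\tGNAS-like\t7\t+
chr1\t4000\t4001\tGNAS-like\t3\t+
chr2\t500\t501\tHK-like\t20\t-
chr2\t700\t701\tHK-like\t9\t-
"""

records = parse_tss_table(io.StringIO(BED6))
table = promoter_profile(records, gap=500)
print(table.to_string(index=False))
# GNAS-like has TSSs at 1000/1200 (one cluster), 2500 and 4000 -> 3 promoters
# (class AP3_4); HK-like's two TSSs are 200 bp apart -> one promoter (SP).
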