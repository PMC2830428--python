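"""Differential Expression Ratio: how often is a gene called DE when measured?

The call matrix is tri-state: 1 = differentially expressed, 0 = measured but
not DE, NA = not measured on that dataset's platform. DER = n_de/n_measured;
genes measured in under 5% of datasets are filtered before any comparison.
"""

from promdiver import compute_der, filter_measured, parse_de_matrix

TSV = (
    "gene_id\tD1\tD2\tD3\tD4\tD5\tD6\n"
    "GA\t1\t1\t0\tNA\t1\t0\n"
    "GB\t0\tNA\t0\tNA\t0\tNA\n"
    "GC\tNA\tNA\tNA\tNA\tNA\t1\n"
)

matrix = parse_de_matrix(TSV)
retained = filter_measured(matrix, min_fraction=0.05)
der = compute_der(matrix)
print(der.to_string(index=False))
print(f"retained after 5% measured filter: {sorted(retained)}")
# GA was DE in 3 of 5 measured datasets (DER 0.6); GB never (0.0); GC was
# measured once, so its ratio (1.0) rests on a single dataset — with 6
# datasets the 5% filter keeps every measured gene (threshold ceil(0.3)=1).
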