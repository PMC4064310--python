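"""qPCR readout of the validation cohort and comparative-Ct normalization.

Simulates a TaqMan-card measurement (Ct values with 0.25-cycle noise,
five housekeeping assays) of the validation cohort restricted to the
screened genes, then converts to expression relative to PPIA.
"""

import dataclasses

from common import DATA, RESULTS, VALIDATION_COHORT

from respanel import comparative_ct_normalize, simulate_ct_table, simulate_expression_cohort
from respanel.datamodel_io import write_ct_table, write_expression_matrix


def main() -> None:
    screened = (RESULTS / "screened_genes.txt").read_text().split()
    validation = simulate_expression_cohort(VALIDATION_COHORT)
    restricted = dataclasses.replace(
        validation,
        expression=validation.expression.subset_genes(sorted(screened)),
        truth=tuple(g for g in validation.truth if g in set(screened)),
    )
    ct = simulate_ct_table(restricted, ct_noise_sd=0.25)
    write_ct_table(ct, DATA / "validation_ct.tsv")

    relative = comparative_ct_normalize(ct, "PPIA").drop_incomplete_genes()
    write_expression_matrix(relative, DATA / "validation_relative_expression.tsv")
    print(f"Ct table: {len(ct.gene_ids)} assays ({len(ct.housekeeping)} housekeeping) "
          f"x {len(ct.sample_ids)} samples")
    print(f"relative expression (2^-dCt vs PPIA): {relative.n_genes} target genes")


if __name__ == "__main__":
    main()
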