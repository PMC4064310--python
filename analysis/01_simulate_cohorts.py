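"""Simulate the two patient cohorts and their clinical covariates.

Writes the test-cohort expression matrix, both cohorts' annotations
(with truncated-normal baseline covariates), and the ground-truth list
of informative genes under results/data/.
"""

from common import DATA, SEED, TEST_COHORT, VALIDATION_COHORT

from respanel import (
    load_clinical_fixture,
    simulate_clinical_covariates,
    simulate_expression_cohort,
)
from respanel.cohortsim import write_truth_genes
from respanel.datamodel_io import write_annotations, write_expression_matrix


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    test = simulate_expression_cohort(TEST_COHORT)
    validation = simulate_expression_cohort(VALIDATION_COHORT)
    annotations = simulate_clinical_covariates(
        test.annotations + validation.annotations,
        load_clinical_fixture(TEST_COHORT.disease), seed=SEED)

    write_expression_matrix(test.expression, DATA / "test_expression.tsv")
    write_expression_matrix(validation.expression, DATA / "validation_expression.tsv")
    write_annotations(annotations, DATA / "annotations.tsv")
    write_truth_genes(test.truth, DATA / "truth_genes.tsv")

    print(f"test cohort: {test.expression.n_genes} genes x "
          f"{test.expression.n_samples} samples "
          f"({TEST_COHORT.n_responders} R / {TEST_COHORT.n_nonresponders} NR)")
    print(f"validation cohort: {validation.expression.n_samples} samples "
          f"({VALIDATION_COHORT.n_responders} R / {VALIDATION_COHORT.n_nonresponders} NR)")
    print(f"informative genes ({len(test.truth)}): {', '.join(test.truth)}")


if __name__ == "__main__":
    main()
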