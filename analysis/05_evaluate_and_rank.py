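"""Rank genes by panel membership and export the best panel's ROC curve.

Restricts to panels with LOOCV accuracy above 80%, counts how often each
gene of the pool appears in them (the candidate-gene ranking for larger
cohorts), and writes the ranking TSV plus ROC points of the best panel.
"""

from common import CV_THRESHOLD, DATA, RESULTS

from respanel import rank_genes_by_panel_membership, roc_curve
from respanel.datamodel_io import labels_for, read_annotations, read_panel_report
from respanel.evaluation import write_ranking, write_roc_points


def main() -> None:
    panels, _ = read_panel_report(RESULTS / "panel_report.json")
    ranking = rank_genes_by_panel_membership(panels, cv_threshold=CV_THRESHOLD)
    write_ranking(ranking, RESULTS / "gene_ranking.tsv")

    annotations = [a for a in read_annotations(DATA / "annotations.tsv")
                   if a.cohort == "validation"]
    best = max(panels, key=lambda p: (p.loocv_accuracy, p.auc))
    scores = [best.loocv_scores[a.sample_id] for a in annotations]
    curve = roc_curve(scores, [a.label for a in annotations])
    write_roc_points(curve, RESULTS / "best_panel_roc.tsv")

    qualifying = sum(p.loocv_accuracy > CV_THRESHOLD for p in panels)
    truth = set((DATA / "truth_genes.tsv").read_text().split()[1:])
    print(f"{qualifying} of {len(panels)} panels clear LOOCV > {CV_THRESHOLD:.0f}%")
    print("top genes by membership in qualifying panels:")
    for gene, count in ranking.entries[:10]:
        marker = " *" if gene in truth else ""
        print(f"  {count:4d}  {gene}{marker}")
    print("  (* = planted informative gene)")
    print(f"best panel ROC-AUC from held-out scores: {curve.auc:.3f}")


if __name__ == "__main__":
    main()
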