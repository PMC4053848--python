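"""Relate SRE scores to Smaug binding and translational repression:
multiple regression of binding on consensus + variant scores, Spearman
correlations, planted-vs-clean medians, the four-class partition and the
bound/repressed overlap.

Writes the coefficient table and an overlap/association report (JSON)
under results/.
"""

import json

import pandas as pd

from common import load_config, outdir
from smaugkit.assoc import (four_class_partition, group_medians,
                            ols_regression, overlap_stats, spearman)
from smaugkit.matrix import ExpressionMatrix
from smaugkit.simulate import rip_enrichment


def main() -> None:
    out = outdir()
    scores = pd.read_csv(out / "sre_scores.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(out / "truth.tsv", sep="\t", index_col=0)
    ti = pd.read_csv(out / "ti_table.tsv", sep="\t", index_col=0)
    rip = ExpressionMatrix.from_tsv(out / "rip.tsv")
    repressed_tab = pd.read_csv(out / "sam_repressed.tsv", sep="\t", index_col=0)
    bound_tab = pd.read_csv(out / "sam_bound.tsv", sep="\t", index_col=0)
    expressed = set(pd.read_csv(out / "expressed_genes.tsv", sep="\t")["gene_id"])

    binding = rip_enrichment(rip)
    reg = ols_regression(binding.loc[scores.index], scores)
    reg.to_csv(out / "regression_coefficients.tsv", sep="\t")
    print("binding ~ SRE-score regression:")
    for name, row in reg.iterrows():
        print(f"  {name:10s} coef {row['coef']:+.3f}  (t={row['t']:+.2f}, p={row['p']:.2g})")

    rho_bind, p_bind = spearman(scores["consensus"], binding.loc[scores.index])
    rho_ti, p_ti = spearman(scores["consensus"], ti["delta_ti"].loc[scores.index])
    print(f"Spearman(consensus score, binding) = {rho_bind:.2f} (p={p_bind:.2g})")
    print(f"Spearman(consensus score, dTI)     = {rho_ti:.2f} (p={p_ti:.2g})")

    labels = truth.loc[scores.index, "is_positive"].map(
        {True: "planted", False: "clean"})
    medians, tests = group_medians(scores["consensus"], labels)
    print(f"median consensus score: planted {medians['planted']:.2f} "
          f"vs clean {medians['clean']:.2f} "
          f"(Wilcoxon p={tests['p'].iloc[0]:.2g})")

    bound = set(bound_tab.index[bound_tab["called"] & (bound_tab["score"] > 0)]) & expressed
    repressed = set(repressed_tab.index[repressed_tab["called"]
                                        & (repressed_tab["score"] > 0)]) & expressed
    report = {
        "spearman_score_binding": round(rho_bind, 3),
        "spearman_score_delta_ti": round(rho_ti, 3),
        "median_score_planted": round(float(medians["planted"]), 3),
        "median_score_clean": round(float(medians["clean"]), 3),
    }
    if bound and repressed:
        overlap = overlap_stats(bound, repressed, expressed)
        classes = four_class_partition(bound, repressed, expressed)
        report["overlap"] = overlap
        report["four_classes"] = {k: len(v) for k, v in classes.items()}
        print(f"bound & repressed overlap: {overlap['n_overlap']} genes "
              f"({overlap['pct_of_a']}% of bound, {overlap['pct_of_b']}% of repressed)")
    with open(out / "association_report.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
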