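"""SAM-style significance calls: expressed genes per pool (one-class),
translationally derepressed genes (two-class on per-replicate TI), and
Smaug-bound genes (two-class on RIP log-ratios).

Writes significance tables and the expressed/bound/repressed gene lists
under results/.
"""

import numpy as np
import pandas as pd

from common import load_config, outdir
from smaugkit.matrix import ExpressionMatrix
from smaugkit.pipeline import (expressed_calls_per_pool, replicate_ti_values,
                               rip_log_ratios)
from smaugkit.sam import expressed_gene_sets, sam_two_class


def main() -> None:
    cfg = load_config()
    n_perm = cfg["sam"]["n_perm"]
    fdr = cfg["sam"]["fdr_cutoff"]
    seed = cfg["simulation"]["seed"]
    out = outdir()

    wt = ExpressionMatrix.from_tsv(out / "polysome_wt_norm.tsv")
    mut = ExpressionMatrix.from_tsv(out / "polysome_mut_norm.tsv")
    rip = ExpressionMatrix.from_tsv(out / "rip.tsv")

    wt_calls = expressed_calls_per_pool(wt, "wt", n_perm=n_perm, seed=seed, fdr_cutoff=fdr)
    mut_calls = expressed_calls_per_pool(mut, "mut", n_perm=n_perm, seed=seed, fdr_cutoff=fdr)
    expressed = expressed_gene_sets(wt_calls, mut_calls)
    print(f"expressed in both genotypes (union of pools, intersected): {len(expressed)}")

    ti_reps = pd.concat([replicate_ti_values(wt, "wt").add_prefix("wt_"),
                         replicate_ti_values(mut, "mut").add_prefix("mut_")],
                        axis=1).loc[sorted(expressed)].dropna()
    labels = [0] * (ti_reps.shape[1] // 2) + [1] * (ti_reps.shape[1] // 2)
    repressed_tab = sam_two_class(ti_reps, labels, n_perm=n_perm, seed=seed, fdr_cutoff=fdr)
    repressed_tab.to_csv(out / "sam_repressed.tsv", sep="\t")
    repressed = repressed_tab[repressed_tab["called"] & (repressed_tab["score"] > 0)]
    print(f"derepressed in the mutant at FDR<{fdr:.0%}: {len(repressed)}")

    ratios, rip_labels = rip_log_ratios(rip)
    bound_tab = sam_two_class(ratios.loc[sorted(expressed & set(ratios.index))],
                              rip_labels, n_perm=n_perm, seed=seed, fdr_cutoff=fdr)
    bound_tab.to_csv(out / "sam_bound.tsv", sep="\t")
    bound = bound_tab[bound_tab["called"] & (bound_tab["score"] > 0)]
    print(f"bound in Smaug vs mock RIPs at FDR<{fdr:.0%}: {len(bound)}")

    pd.Series(sorted(expressed), name="gene_id").to_csv(
        out / "expressed_genes.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
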