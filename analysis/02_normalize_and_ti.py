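"""Normalize the polysome matrices (quantile, then spike-in rescaling) and
compute per-gene translation indices and their mutant-vs-wild-type shift.

Writes the normalized matrices and the TI table (TI_wt, TI_mut, dTI, rank)
under results/.
"""

import numpy as np

from common import load_config, outdir
from smaugkit.matrix import ExpressionMatrix
from smaugkit.normalize import normalize_pipeline
from smaugkit.ti import format_fold_change, ti_table


def main() -> None:
    out = outdir()
    wt = normalize_pipeline(ExpressionMatrix.from_tsv(out / "polysome_wt.tsv"))
    mut = normalize_pipeline(ExpressionMatrix.from_tsv(out / "polysome_mut.tsv"))
    wt.to_tsv(out / "polysome_wt_norm.tsv")
    mut.to_tsv(out / "polysome_mut_norm.tsv")

    tab = ti_table(wt, mut)
    tab.to_csv(out / "ti_table.tsv", sep="\t")

    top = tab.sort_values("rank").head(5)
    print(f"TI computed for {len(tab)} genes")
    print(f"median dTI: {tab['delta_ti'].median():+.2f} log2 units")
    for gid, row in top.iterrows():
        print(f"  rank {int(row['rank']):3d}  {gid}  dTI {row['delta_ti']:+.2f} "
              f"(linear fold-change {format_fold_change(row['delta_ti']):.2f})")


if __name__ == "__main__":
    main()
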