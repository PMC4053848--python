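"""Score transcripts for SRE stem-loops: two-stage scan (local pair-
probability prescan, then Boltzmann-ensemble sampling over 36 windows per
candidate site) for the consensus CNGG loop and selected variants.

Writes the per-transcript score table under results/.  This is the
thermodynamically heavy step; the number of scored genes and samples per
window are set in the config.
"""

import numpy as np

from common import load_config, outdir
from smaugkit.fold import FoldingModel
from smaugkit.pipeline import score_sre_subset
from smaugkit.simulate import TranscriptSet
from smaugkit.sre import VariantSpec


def main() -> None:
    cfg = load_config()
    seed = cfg["simulation"]["seed"]
    sre_cfg = cfg["sre"]
    out = outdir()

    transcripts = TranscriptSet.read(out / "transcripts.fasta",
                                     out / "transcript_regions.tsv")
    # truth-stratified subset: planted and clean genes in cohort proportion
    import pandas as pd
    truth = pd.read_csv(out / "truth.tsv", sep="\t", index_col=0)
    rng = np.random.default_rng([seed, 404])
    pos = list(truth.index[truth["is_positive"]])
    neg = list(truth.index[~truth["is_positive"]])
    n_total = sre_cfg["n_genes_scored"]
    n_pos = min(len(pos), max(1, int(n_total * len(pos) / len(truth))))
    subset = sorted(rng.choice(pos, n_pos, replace=False).tolist()
                    + rng.choice(neg, min(len(neg), n_total - n_pos),
                                 replace=False).tolist())

    variants = {v: VariantSpec(pattern=v) for v in sre_cfg["variants"]}
    scores = score_sre_subset(transcripts, subset, FoldingModel(),
                              n_samples=sre_cfg["n_samples"], seed=seed,
                              variants=variants)
    scores.to_csv(out / "sre_scores.tsv", sep="\t")

    planted = scores.loc[scores.index.isin(pos), "consensus"]
    clean = scores.loc[scores.index.isin(neg), "consensus"]
    print(f"scored {len(scores)} transcripts "
          f"({len(planted)} planted, {len(clean)} clean)")
    print(f"median consensus SRE score: planted {planted.median():.2f}, "
          f"clean {clean.median():.2f}")


if __name__ == "__main__":
    main()
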