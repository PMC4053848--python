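"""End-to-end synthetic study: simulate -> normalize -> TI -> SAM calls ->
target-count deconvolution -> SRE scoring -> association.

The heavy thermodynamic scoring is run on a configurable subset of genes;
everything else runs on the full simulated cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, deconvolve, normalize, sam, sre, ti
from .fold import FoldingModel
from .matrix import ExpressionMatrix
from .simulate import (SimulationConfig, TranscriptSet, generate_transcriptome,
                       rip_enrichment, simulate_polysome, simulate_rip)

LOG2_BACKGROUND = 6.0  # background intensity level for expressed-gene calls


def replicate_ti_values(m: ExpressionMatrix, genotype: str) -> pd.DataFrame:
    """Per-replicate TI values (genes x replicates) for two-class SAM."""
    vals = m.values.loc[m.assay_ids]
    meta = m.sample_meta()
    reps = sorted(meta.loc[meta["genotype"] == genotype, "replicate"].dropna().unique())
    out = {}
    for rep in reps:
        pools = {p: vals[m.columns_where(genotype=genotype, pool=p, replicate=rep)[0]]
                 for p in range(1, 5)}
        out[f"rep{int(rep)}"] = ti.compute_ti(pools[1], pools[2], pools[3], pools[4])
    return pd.DataFrame(out, index=vals.index)


def expressed_calls_per_pool(m: ExpressionMatrix, genotype: str,
                             n_perm: int = 1000, seed: int = 0,
                             fdr_cutoff: float = 0.05) -> dict[int, set]:
    """One-class SAM per pool on log2 signal over background."""
    vals = m.values.loc[m.assay_ids]
    calls = {}
    for pool in range(1, 5):
        cols = m.columns_where(genotype=genotype, pool=pool)
        logv = np.log2(np.maximum(vals[cols], 1e-9)) - LOG2_BACKGROUND
        table = sam.sam_one_class(logv, n_perm=n_perm, seed=seed, fdr_cutoff=fdr_cutoff)
        calls[pool] = set(table.index[table["called"] & (table["score"] > 0)])
    return calls


def rip_log_ratios(rip: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """log2(IP/input) per replicate for mock and Smaug IPs, with 0/1 labels
    (mock = 0, Smaug = 1) for two-class SAM."""
    vals = rip.values.loc[rip.assay_ids]
    meta = rip.sample_meta()
    reps = sorted(meta["replicate"].dropna().unique())
    cols, labels = {}, []
    for role, lab in (("mock_ip", 0), ("smaug_ip", 1)):
        for rep in reps:
            ratio = np.log2(vals[f"{role}_rep{int(rep)}"]) - np.log2(vals[f"input_rep{int(rep)}"])
            cols[f"{role}_rep{int(rep)}"] = ratio
            labels.append(lab)
    return pd.DataFrame(cols, index=vals.index), np.array(labels)


def score_sre_subset(transcripts: TranscriptSet, gene_ids, model: FoldingModel,
                     n_samples: int = 300, seed: int = 0,
                     variants: dict[str, sre.VariantSpec] | None = None) -> pd.DataFrame:
    """Consensus (and optional variant) SRE scores for a subset of genes."""
    by_id = transcripts.by_id()
    specs = {"consensus": sre.CONSENSUS}
    specs.update(variants or {})
    rows = []
    for gid in gene_ids:
        t = by_id[gid]
        row = {"gene_id": gid}
        for name, spec in specs.items():
            score = sre.transcript_sre_score(
                t.sequence, model, spec=spec, n_samples=n_samples, seed=seed,
                transcript_id=gid, utr5_end=t.utr5_end, orf_end=t.orf_end)
            row[name] = score.total
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def run_end_to_end(cfg: SimulationConfig, n_perm: int = 200,
                   reference_sizes=(250, 500, 1000), sre_genes: int = 100,
                   sre_samples: int = 300, fdr_cutoff: float = 0.05,
                   model: FoldingModel | None = None) -> dict:
    """One config, one seed; returns every intermediate product keyed by
    stage name."""
    model = model or FoldingModel()
    seed = cfg.seed

    transcripts = generate_transcriptome(cfg)
    wt, mut, truth = simulate_polysome(transcripts, cfg)
    rip = simulate_rip(transcripts, cfg)

    wt_n = normalize.normalize_pipeline(wt)
    mut_n = normalize.normalize_pipeline(mut)

    ti_tab = ti.ti_table(wt_n, mut_n)

    wt_calls = expressed_calls_per_pool(wt_n, "wt", n_perm=n_perm, seed=seed)
    mut_calls = expressed_calls_per_pool(mut_n, "mut", n_perm=n_perm, seed=seed)
    expressed = sam.expressed_gene_sets(wt_calls, mut_calls) & set(ti_tab.index)

    # two-class dTI calls (wild type vs mutant per-replicate TI)
    ti_reps = pd.concat([replicate_ti_values(wt_n, "wt").add_prefix("wt_"),
                         replicate_ti_values(mut_n, "mut").add_prefix("mut_")], axis=1)
    ti_reps = ti_reps.loc[sorted(expressed)].dropna()
    labels = np.array([0] * (ti_reps.shape[1] // 2) + [1] * (ti_reps.shape[1] // 2))
    repressed_tab = sam.sam_two_class(ti_reps, labels, n_perm=n_perm, seed=seed,
                                      fdr_cutoff=fdr_cutoff)
    repressed = set(repressed_tab.index[repressed_tab["called"]
                                        & (repressed_tab["score"] > 0)])

    # RIP two-class: Smaug IP/input vs mock IP/input
    ratios, rip_labels = rip_log_ratios(rip)
    bound_tab = sam.sam_two_class(ratios.loc[sorted(expressed & set(ratios.index))],
                                  rip_labels, n_perm=n_perm, seed=seed,
                                  fdr_cutoff=fdr_cutoff)
    bound = set(bound_tab.index[bound_tab["called"] & (bound_tab["score"] > 0)])

    binding = rip_enrichment(rip)
    ranking = list(binding.loc[sorted(expressed & set(binding.index))]
                   .sort_values(ascending=False).index)
    sizes = [n for n in reference_sizes if n <= len(ranking) // 2]
    estimates = deconvolve.estimate_over_reference_sizes(
        ti_tab["delta_ti"].loc[ranking], ranking, sizes)

    # SRE scoring on a truth-stratified subset (keeps folding cost bounded)
    rng = np.random.default_rng([seed, 404])
    pos_ids = [t.id for t in transcripts if t.planted_sites]
    neg_ids = [t.id for t in transcripts if not t.planted_sites]
    n_pos = min(len(pos_ids), max(1, int(sre_genes * cfg.frac_positives)))
    n_neg = min(len(neg_ids), sre_genes - n_pos)
    subset = sorted(rng.choice(pos_ids, n_pos, replace=False).tolist()
                    + rng.choice(neg_ids, n_neg, replace=False).tolist())
    scores = score_sre_subset(transcripts, subset, model,
                              n_samples=sre_samples, seed=seed)

    regression = assoc.ols_regression(binding.loc[scores.index], scores)
    rho, rho_p = assoc.spearman(scores["consensus"],
                                ti_tab["delta_ti"].loc[scores.index])
    labels_sub = truth.loc[scores.index, "is_positive"].map(
        {True: "planted", False: "clean"})
    medians, median_tests = assoc.group_medians(scores["consensus"], labels_sub)

    classes = assoc.four_class_partition(bound & expressed, repressed & expressed,
                                         expressed)
    overlaps = assoc.overlap_stats(bound, repressed, expressed) \
        if (bound and repressed) else None

    return {
        "transcripts": transcripts,
        "truth": truth,
        "matrices": {"wt": wt_n, "mut": mut_n, "rip": rip},
        "ti": ti_tab,
        "expressed": expressed,
        "repressed_table": repressed_tab,
        "repressed": repressed,
        "bound_table": bound_tab,
        "bound": bound,
        "binding": binding,
        "estimates": estimates,
        "sre_scores": scores,
        "regression": regression,
        "spearman": (rho, rho_p),
        "sre_medians": medians,
        "sre_median_tests": median_tests,
        "four_classes": classes,
        "overlaps": overlaps,
    }
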