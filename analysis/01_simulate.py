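"""Generate the synthetic study: transcriptome with planted SRE hairpins,
polysome-pool matrices for wild type and mutant, and the RIP-Chip matrix.

Writes FASTA + region sidecar, intensity TSVs, and the ground-truth table
under results/.
"""

from common import load_config, outdir, simulation_config
from smaugkit.simulate import (generate_transcriptome, simulate_polysome,
                               simulate_rip)


def main() -> None:
    cfg = simulation_config(load_config())
    out = outdir()

    transcripts = generate_transcriptome(cfg)
    wt, mut, truth = simulate_polysome(transcripts, cfg)
    rip = simulate_rip(transcripts, cfg)

    transcripts.write_fasta(out / "transcripts.fasta")
    transcripts.write_regions(out / "transcript_regions.tsv")
    wt.to_tsv(out / "polysome_wt.tsv")
    mut.to_tsv(out / "polysome_mut.tsv")
    rip.to_tsv(out / "rip.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")

    n_pos = len(transcripts.positives())
    print(f"simulated {len(transcripts)} transcripts "
          f"({n_pos} with planted SREs, {len(transcripts) - n_pos} clean)")
    print(f"polysome matrices: {wt.values.shape[1]} samples each "
          f"({len(wt.spikein_ids)} spike-in rows); RIP matrix: "
          f"{rip.values.shape[1]} samples")


if __name__ == "__main__":
    main()
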