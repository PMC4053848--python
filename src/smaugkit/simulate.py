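"""Synthetic transcriptomes and microarray matrices with known ground truth.

The generator emulates the experimental design of a polysome-gradient /
RIP-Chip study of a Smaug-type repressor in the early embryo:

* transcripts are compact minigenes (5'UTR / ORF / 3'UTR) over {A,C,G,U};
  a configurable fraction of "positive" genes carries one or more planted
  SRE hairpins (strong complementary stem, CNGGN loop), the rest are
  screened against accidental strong SREs;
* polysome matrices have 4 pools x 3 replicates per genotype, spike-in
  rows with known constant abundances, per-sample scale factors and
  lognormal measurement noise; each gene's pool allocation is chosen so
  that the noise-free translation index equals a drawn TI, and the
  mutant-vs-wild-type TI shift follows a two-component mixture (positives
  shifted up, negatives centred at zero);
* RIP matrices have Smaug IP / mock IP / input roles with 4 replicates
  (3 biological + 1 technical) and IP enrichment growing with the number
  of planted sites;
* a puromycin treatment can be applied in silico by releasing polysomal
  (pools 3-4) mass into pool 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

_ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    id: str
    sequence: str
    utr5_end: int
    orf_end: int
    planted_sites: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.utr5_end <= self.orf_end <= len(self.sequence)):
            raise ValueError(f"bad region boundaries for {self.id}")
        if set(self.sequence) - set(_ALPHABET):
            raise ValueError(f"non-ACGU sequence in {self.id}")
        for pos, loop in self.planted_sites:
            if self.sequence[pos:pos + len(loop)] != loop:
                raise ValueError(f"planted loop mismatch at {pos} in {self.id}")
            if not _loop_matches_consensus(loop):
                raise ValueError(f"planted loop {loop!r} violates CNGGN0-4")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptSet:
    transcripts: list[Transcript]

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self):
        return len(self.transcripts)

    def __getitem__(self, i):
        return self.transcripts[i]

    def by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}

    def positives(self) -> list[str]:
        return [t.id for t in self.transcripts if t.planted_sites]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.id}\n{t.sequence}\n")

    def write_regions(self, path: str | Path) -> None:
        rows = [{"id": t.id, "utr5_end": t.utr5_end, "orf_end": t.orf_end}
                for t in self.transcripts]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta: str | Path, regions: str | Path) -> "TranscriptSet":
        from Bio import SeqIO
        reg = pd.read_csv(regions, sep="\t").set_index("id")
        ts = []
        for rec in SeqIO.parse(str(fasta), "fasta"):
            r = reg.loc[rec.id]
            ts.append(Transcript(rec.id, str(rec.seq).upper().replace("T", "U"),
                                 int(r["utr5_end"]), int(r["orf_end"])))
        return cls(ts)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    frac_positives: float = 0.3
    positive_shift_mean: float = 1.5   # log2 TI shift of repressed genes in the mutant
    positive_shift_sd: float = 0.4
    negative_sd: float = 0.4           # log2 TI shift spread of unaffected genes
    noise_sd: float = 0.15             # lognormal measurement noise, log2 units
    n_spikeins: int = 8
    seed: int = 0
    # transcript architecture
    composition: tuple = (0.45, 0.10, 0.10, 0.35)  # A, C, G, U background
    utr5_len: int = 45
    orf_len: int = 70
    utr3_len: int = 45
    stem_len: int = 5
    max_planted: int = 3
    # expression model
    wt_ti_sd: float = 1.0
    abundance_log2_mean: float = 10.0
    abundance_log2_sd: float = 1.0
    pool2_share: float = 0.1
    scale_sd: float = 0.2              # per-sample scale factor spread, log2 units
    n_replicates: int = 3
    rip_beta: float = 1.0              # log2 IP enrichment per planted site
    rip_replicates: int = 4            # 3 biological + 1 technical

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_positives <= 1.0:
            raise ValueError("frac_positives must be in [0, 1]")
        for name in ("positive_shift_sd", "negative_sd", "noise_sd", "scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.pool2_share < 1.0:
            raise ValueError("pool2_share must be in [0, 1)")
        if len(self.composition) != 4 or abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must be 4 base frequencies summing to 1")

    @property
    def transcript_len(self) -> int:
        return self.utr5_len + self.orf_len + self.utr3_len


def _loop_matches_consensus(loop: str) -> bool:
    return (4 <= len(loop) <= 8 and loop[0] == "C" and loop[2:4] == "GG"
            and not set(loop) - set(_ALPHABET))


def plant_hairpin(sequence: str, position: int, loop: str, stem_len: int,
                  stem: str | None = None) -> str:
    """Replace bases around ``position`` (loop start) with a stem-loop:
    ``stem + loop + revcomp(stem)``.  Length-preserving."""
    if not _loop_matches_consensus(loop):
        raise ValueError(f"loop {loop!r} does not match the CNGGN0-4 consensus")
    if stem is None:
        # default stem: strong GC-only pattern with a dominant register and
        # no internal CNGG motif
        stem = ("CGCGG" * (stem_len // 5 + 1))[:stem_len]
    if len(stem) != stem_len:
        raise ValueError("stem length mismatch")
    start = position - stem_len
    end = position + len(loop) + stem_len
    if start < 0 or end > len(sequence):
        raise ValueError("hairpin does not fit within the sequence")
    return sequence[:start] + stem + loop + revcomp(stem) + sequence[end:]


def _random_seq(rng: np.random.Generator, length: int,
                composition=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list(_ALPHABET), size=length, p=composition))


def _has_accidental_sre(seq: str, min_stack: int = 2) -> bool:
    """Fast string heuristic for a strong accidental SRE: a CNGG whose
    5'-flank base closes a loop of 4-8 nt with >= ``min_stack`` additional
    stacked complementary pairs."""
    n = len(seq)
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
    for p in range(1, n - 4):
        if not (seq[p] == "C" and seq[p + 2:p + 4] == "GG"):
            continue
        for j in range(p + 4, min(p + 9, n)):
            if (seq[p - 1], seq[j]) not in pairs:
                continue
            stack = 0
            k = 1
            while p - 1 - k >= 0 and j + k < n and (seq[p - 1 - k], seq[j + k]) in pairs:
                stack += 1
                k += 1
            if stack >= min_stack:
                return True
    return False


def _random_loop(rng: np.random.Generator) -> str:
    # CNGGN0-4 consensus; lengths weighted toward the 5-nt loop that the
    # field reports as the best performer
    length = int(rng.choice([4, 5, 5, 5, 6, 7, 8]))
    bases = list(_ALPHABET)
    loop = "C" + str(rng.choice(bases)) + "GG"
    loop += "".join(rng.choice(bases) for _ in range(length - 4))
    return loop


def generate_transcriptome(cfg: SimulationConfig) -> TranscriptSet:
    """Random minigene transcripts; a ``frac_positives`` subset carries
    planted SRE hairpins, the rest are screened against accidental sites."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 101])
    n_pos = int(round(cfg.n_genes * cfg.frac_positives))
    pos_idx = set(rng.choice(cfg.n_genes, size=n_pos, replace=False).tolist())
    length = cfg.transcript_len
    transcripts = []
    for g in range(cfg.n_genes):
        gid = f"g{g:05d}"
        if g in pos_idx:
            n_sites = int(rng.integers(1, cfg.max_planted + 1))
            for _ in range(200):
                seq = _random_seq(rng, length, cfg.composition)
                sites = _plant_sites(seq, rng, cfg, n_sites)
                if sites is not None:
                    seq, planted = sites
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not place planted hairpins")
            transcripts.append(Transcript(gid, seq, cfg.utr5_len,
                                          cfg.utr5_len + cfg.orf_len, planted))
        else:
            for _ in range(200):
                seq = _random_seq(rng, length, cfg.composition)
                if not _has_accidental_sre(seq):
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw a clean negative sequence")
            transcripts.append(Transcript(gid, seq, cfg.utr5_len,
                                          cfg.utr5_len + cfg.orf_len))
    return TranscriptSet(transcripts)


def _plant_sites(seq: str, rng: np.random.Generator, cfg: SimulationConfig,
                 n_sites: int):
    """Place ``n_sites`` non-overlapping hairpins; returns (seq, sites) or
    None if placement failed for this backbone."""
    length = len(seq)
    occupied: list[tuple[int, int]] = []
    planted = []
    for _ in range(n_sites):
        placed = False
        for _ in range(50):
            loop = _random_loop(rng)
            extent = cfg.stem_len * 2 + len(loop)
            pos = int(rng.integers(cfg.stem_len + 5, length - extent - 5))
            lo, hi = pos - cfg.stem_len - 3, pos + len(loop) + cfg.stem_len + 3
            if any(not (hi <= a or lo >= b) for a, b in occupied):
                continue
            seq = plant_hairpin(seq, pos, loop, cfg.stem_len)
            occupied.append((lo, hi))
            planted.append((pos, loop))
            placed = True
            break
        if not placed:
            return None
    planted.sort()
    return seq, planted


# ---------------------------------------------------------------------------
# expression matrices

def _spikein_levels(cfg: SimulationConfig) -> np.ndarray:
    # geometric ladder of known abundances spanning ~2 decades
    return 2.0 ** np.linspace(7.0, 13.0, cfg.n_spikeins)


def _noisy(rng: np.random.Generator, mass: np.ndarray, scale: float,
           noise_sd: float) -> np.ndarray:
    noise = 2.0 ** rng.normal(0.0, noise_sd, size=mass.shape) if noise_sd > 0 else 1.0
    return mass * scale * noise


def simulate_polysome(transcripts: TranscriptSet, cfg: SimulationConfig
                      ) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Wild-type and mutant polysome-pool matrices plus the truth table."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 202])
    gene_ids = [t.id for t in transcripts]
    n = len(gene_ids)
    is_pos = np.array([bool(t.planted_sites) for t in transcripts])

    abundance = 2.0 ** rng.normal(cfg.abundance_log2_mean, cfg.abundance_log2_sd, n)
    wt_ti = rng.normal(0.0, cfg.wt_ti_sd, n)
    delta = np.where(is_pos,
                     rng.normal(cfg.positive_shift_mean, cfg.positive_shift_sd, n),
                     rng.normal(0.0, cfg.negative_sd, n))
    mut_ti = wt_ti + delta

    spike_ids = [f"spikein_{k+1}" for k in range(cfg.n_spikeins)]
    spike_mass = _spikein_levels(cfg)

    def pools_for(ti: np.ndarray) -> np.ndarray:
        r = 2.0 ** ti
        rem = (1.0 - cfg.pool2_share) * abundance
        p1 = rem / (1.0 + 2.0 * r)
        p3 = r * p1
        return np.column_stack([p1, cfg.pool2_share * abundance, p3, p3])

    matrices = {}
    for genotype, ti in (("wt", wt_ti), ("mut", mut_ti)):
        pools = pools_for(ti)
        cols = {}
        for rep in range(1, cfg.n_replicates + 1):
            for pool in range(1, 5):
                scale = 2.0 ** rng.normal(0.0, cfg.scale_sd) if cfg.scale_sd > 0 else 1.0
                gene_vals = _noisy(rng, pools[:, pool - 1], scale, cfg.noise_sd)
                spk_vals = _noisy(rng, spike_mass, scale, cfg.noise_sd)
                cols[f"{genotype}_pool{pool}_rep{rep}"] = np.concatenate([gene_vals, spk_vals])
        df = pd.DataFrame(cols, index=gene_ids + spike_ids)
        matrices[genotype] = ExpressionMatrix(df, spike_ids)

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_positive": is_pos,
        "n_planted": [len(t.planted_sites) for t in transcripts],
        "wt_ti": wt_ti,
        "delta_ti": delta,
    }).set_index("gene_id")
    return matrices["wt"], matrices["mut"], truth


def simulate_rip(transcripts: TranscriptSet, cfg: SimulationConfig) -> ExpressionMatrix:
    """Smaug IP / mock IP / input matrix; IP enrichment grows with the
    number of planted SRE sites."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 303])
    gene_ids = [t.id for t in transcripts]
    n = len(gene_ids)
    sites = np.array([len(t.planted_sites) for t in transcripts], dtype=float)
    abundance = 2.0 ** rng.normal(cfg.abundance_log2_mean, cfg.abundance_log2_sd, n)
    cols = {}
    for rep in range(1, cfg.rip_replicates + 1):
        for role, mass in (("input", abundance),
                           ("smaug_ip", abundance * 2.0 ** (cfg.rip_beta * sites)),
                           ("mock_ip", abundance)):
            scale = 2.0 ** rng.normal(0.0, cfg.scale_sd) if cfg.scale_sd > 0 else 1.0
            cols[f"{role}_rep{rep}"] = _noisy(rng, mass, scale, cfg.noise_sd)
    return ExpressionMatrix(pd.DataFrame(cols, index=gene_ids))


def rip_enrichment(rip: ExpressionMatrix) -> pd.Series:
    """Per-gene mean log2(Smaug IP / mock IP), the binding metric used to
    rank Smaug binders."""
    vals = rip.values.loc[rip.assay_ids]
    meta = rip.sample_meta()
    reps = sorted(meta["replicate"].dropna().unique())
    enr = []
    for rep in reps:
        ip = vals[f"smaug_ip_rep{rep}"]
        mock = vals[f"mock_ip_rep{rep}"]
        enr.append(np.log2(ip) - np.log2(mock))
    return pd.concat(enr, axis=1).mean(axis=1)


def simulate_puromycin(matrix: ExpressionMatrix, release_frac: float = 0.9
                       ) -> ExpressionMatrix:
    """In-silico puromycin run-off: move ``release_frac`` of pools 3-4 mass
    into pool 1, per replicate column set."""
    if not 0.0 <= release_frac <= 1.0:
        raise ValueError("release_frac must be in [0, 1]")
    vals = matrix.values.copy()
    meta = matrix.sample_meta()
    groups = meta.dropna(subset=["pool"]).groupby(["genotype", "replicate"])
    for (_, _), sub in groups:
        bypool = {int(p): s for p, s in zip(sub["pool"], sub.index)}
        if set(bypool) != {1, 2, 3, 4}:
            continue
        released = release_frac * (vals[bypool[3]] + vals[bypool[4]])
        vals[bypool[1]] = vals[bypool[1]] + released
        vals[bypool[3]] = (1.0 - release_frac) * vals[bypool[3]]
        vals[bypool[4]] = (1.0 - release_frac) * vals[bypool[4]]
    return matrix.with_values(vals)


def noise_free(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of the config with measurement noise and scale factors off."""
    return replace(cfg, noise_sd=0.0, scale_sd=0.0)
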