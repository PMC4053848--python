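"""SRE (Smaug recognition element) search and scoring.

Two-stage procedure over a transcript:

1. *Prescan* — locally averaged pair probabilities (sliding 170-nt windows,
   pair span <= 120 nt) mark a CNGG occurrence as a candidate site when the
   base immediately 5' of the 4-mer can close a hairpin with one of the
   five bases immediately 3' of it with probability > 0.01.
2. *Scoring* — for each candidate, 36 overlapping windows are built (the
   5'-most spans 75 nt upstream of the site through 40 nt downstream, the
   3'-most 40 nt upstream through 75 nt downstream, the rest offset by one
   nucleotide).  In each window structures are sampled from the Boltzmann
   ensemble and the empirical fraction in which the site sits at the 5' end
   of a hairpin loop of 4-8 nt is recorded; the site probability is the
   mean over windows.  A transcript's SRE score is the sum of its site
   probabilities, also broken down by region (5'UTR / ORF / 3'UTR).

Loop variants (e.g. CAGG, a fixed closing-base identity, an exact loop
length) run through the identical pipeline with the constraint substituted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .fold import FoldingModel, PartitionResult, _CANONICAL, _validate_seq, local_pair_probabilities


@dataclass(frozen=True)
class VariantSpec:
    """Loop-motif specification; the consensus is CNGG, loop length 4-8,
    any closing-base identity."""

    pattern: str = "CNGG"           # 4-mer, N = any base
    loop_min: int = 4
    loop_max: int = 8
    closing_base: str | None = None  # required identity of the base 5' of the loop

    def __post_init__(self) -> None:
        if len(self.pattern) != 4 or set(self.pattern) - set("ACGUN"):
            raise ValueError(f"malformed 4-mer pattern: {self.pattern!r}")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("invalid loop length range")
        if self.closing_base is not None and self.closing_base not in "ACGU":
            raise ValueError("closing_base must be one of A, C, G, U")

    @property
    def regex(self) -> re.Pattern:
        return re.compile("(?=(" + self.pattern.replace("N", "[ACGU]") + "))")


CONSENSUS = VariantSpec()


@dataclass
class SreSiteScore:
    transcript_id: str
    site_pos: int                 # 0-based offset of the first base of the 4-mer
    window_probs: list[float]
    region: str                   # "5UTR" / "ORF" / "3UTR"

    @property
    def site_prob(self) -> float:
        return float(np.mean(self.window_probs))


@dataclass
class SreScore:
    transcript_id: str
    sites: list[SreSiteScore] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(sum(s.site_prob for s in self.sites))

    def region_total(self, region: str) -> float:
        return float(sum(s.site_prob for s in self.sites if s.region == region))


def is_sre(structure: str, site_pos: int, spec: VariantSpec = CONSENSUS) -> bool:
    """True iff the site base is the 5'-most unpaired base of a hairpin loop
    of admissible length, closed by the pair joining the bases flanking the
    loop."""
    pairmap = {}
    stack: list[int] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            i = stack.pop()
            pairmap[i] = idx
            pairmap[idx] = i
    return _pairs_form_sre(pairmap, site_pos, len(structure), spec)


def _pairs_form_sre(pairmap: dict[int, int], p: int, n: int, spec: VariantSpec) -> bool:
    if p < 1:
        return False
    j = pairmap.get(p - 1)
    if j is None or j <= p:
        return False
    loop_len = j - p
    if not (spec.loop_min <= loop_len <= spec.loop_max):
        return False
    # hairpin: every base strictly inside the closing pair is unpaired
    return all(q not in pairmap for q in range(p, j))


def scan_candidates(seq: str, pair_probs: np.ndarray, threshold: float = 0.01,
                    spec: VariantSpec = CONSENSUS) -> list[int]:
    """Positions of motif occurrences whose 5'-flank base closes a hairpin
    with one of the five downstream bases with probability > threshold."""
    seq = _validate_seq(seq)
    n = len(seq)
    out = []
    for match in spec.regex.finditer(seq):
        p = match.start()
        if p < 1 or p + 4 > n - 1:
            continue  # too close to a transcript end to form a closed loop
        if spec.closing_base is not None and seq[p - 1] != spec.closing_base:
            continue
        best = 0.0
        for j in range(p + 4, min(p + 9, n)):
            if (seq[p - 1], seq[j]) in _CANONICAL:
                best = max(best, float(pair_probs[p - 1, j]))
        if best > threshold:
            out.append(p)
    return out


# window geometry: 5'-most window = [p - UP, site_end + DOWN), 3'-most
# window = [p - DOWN, site_end + UP); one-nucleotide offsets in between.
UPSTREAM = 75
DOWNSTREAM = 40


def site_windows(site_pos: int, seq_len: int, up: int = UPSTREAM,
                 down: int = DOWNSTREAM, site_len: int = 4) -> list[tuple[int, int]]:
    """Half-open [start, end) windows overlapping a candidate site,
    truncated at transcript boundaries."""
    out = []
    for k in range(0, up - down + 1):
        start = site_pos - up + k
        end = site_pos + site_len + down + k
        out.append((max(0, start), min(seq_len, end)))
    return out


def site_probability(seq: str, site_pos: int, model: FoldingModel | None = None,
                     n_samples: int = 3000, up: int = UPSTREAM, down: int = DOWNSTREAM,
                     seed: int = 0, spec: VariantSpec = CONSENSUS,
                     transcript_id: str = "", region: str = "") -> SreSiteScore:
    """Empirical SRE-formation probability of one candidate site, averaged
    over the overlapping sampling windows.  Per-window random streams are
    derived from (seed, site_pos, window index), so results do not depend
    on the order in which sites are scored."""
    model = model or FoldingModel()
    seq = _validate_seq(seq)
    n = len(seq)
    if not (0 <= site_pos and site_pos + 4 <= n):
        raise ValueError("site outside transcript")
    window_probs = []
    for w_idx, (start, end) in enumerate(site_windows(site_pos, n, up, down)):
        sub = seq[start:end]
        local_pos = site_pos - start
        if local_pos < 1 or site_pos + 4 > end:
            window_probs.append(0.0)
            continue
        res = PartitionResult(sub, model)
        rng = np.random.default_rng([seed, site_pos, w_idx])
        hits = 0
        for pairs in res.sample_pairs(n_samples, rng):
            pairmap = {}
            for a, b in pairs:
                pairmap[a] = b
                pairmap[b] = a
            if _pairs_form_sre(pairmap, local_pos, len(sub), spec):
                hits += 1
        window_probs.append(hits / n_samples)
    return SreSiteScore(transcript_id, site_pos, window_probs, region)


def _region_of(pos: int, utr5_end: int, orf_end: int) -> str:
    if pos < utr5_end:
        return "5UTR"
    if pos < orf_end:
        return "ORF"
    return "3UTR"


def transcript_sre_score(seq: str, model: FoldingModel | None = None,
                         spec: VariantSpec = CONSENSUS, n_samples: int = 3000,
                         threshold: float = 0.01, window: int = 170,
                         max_span: int = 120, seed: int = 0,
                         transcript_id: str = "", utr5_end: int = 0,
                         orf_end: int = 0) -> SreScore:
    """Full two-stage scan of one transcript: prescan candidates, score
    each by ensemble sampling, sum site probabilities."""
    model = model or FoldingModel()
    seq = _validate_seq(seq)
    probs = local_pair_probabilities(seq, model, window=window, max_span=max_span)
    score = SreScore(transcript_id)
    for p in scan_candidates(seq, probs, threshold=threshold, spec=spec):
        site = site_probability(seq, p, model, n_samples=n_samples, seed=seed,
                                spec=spec, transcript_id=transcript_id,
                                region=_region_of(p, utr5_end, orf_end))
        score.sites.append(site)
    return score


def variant_score(seq: str, variant: VariantSpec, **kwargs) -> SreScore:
    """Identical pipeline with a variant loop specification."""
    return transcript_sre_score(seq, spec=variant, **kwargs)
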