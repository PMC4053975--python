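"""Chromatogram-based editing quantification and editing-aware miRNA seed scanning.

A-to-I editing shows up in Sanger chromatograms as a dual A/G peak; the
editing percentage is the G peak height divided by the A+G peak heights,
times 100, and is classified into five levels (non, low, medium, high,
full). Because inosine is read as guanosine, an edited adenosine can make
or break miRNA seed pairing in a 3'UTR; the seed scanner pairs every
target heptamer antiparallel against miRNA positions 2-8, allowing a
configurable number of G:U wobble pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

LEVELS = ("non", "low", "medium", "high", "full")
# lower-inclusive boundaries; 'full' also includes 100
_LEVEL_BOUNDS = ((0, 10), (10, 25), (25, 50), (50, 75), (75, 100))

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

SEED_LEN = 7  # miRNA positions 2-8


@dataclass
class PeakHeights:
    """Peak heights for A, C, G, T at one chromatogram position."""

    A: float
    C: float
    G: float
    T: float

    def __post_init__(self) -> None:
        if min(self.A, self.C, self.G, self.T) < 0:
            raise ValueError("peak heights must be non-negative")


@dataclass
class SeedMatch:
    target_name: str
    start: int  # 0-based half-open window on the target (sense strand)
    end: int
    pairing: tuple  # labels for miRNA positions 2..8, each WC/wobble/mismatch
    n_wc: int
    n_wobble: int


def editing_percent(peaks: PeakHeights) -> float:
    """Editing percentage from A and G peak heights: 100*G/(A+G)."""
    if peaks.A + peaks.G == 0:
        raise ValueError("no A or G signal at this position")
    return 100.0 * peaks.G / (peaks.A + peaks.G)


def classify_level(percent: float) -> str:
    """Five-level editing class: non [0,10), low [10,25), medium [25,50),
    high [50,75), full [75,100]."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent {percent} outside [0, 100]")
    if percent == 100:
        return "full"
    for level, (lo, hi) in zip(LEVELS, _LEVEL_BOUNDS):
        if lo <= percent < hi:
            return level
    return "full"


def replicate_summary(percents_a, percents_b) -> dict:
    """Group means/SDs and a two-tailed two-sample t-test across replicates."""
    a = np.asarray(percents_a, dtype=float)
    b = np.asarray(percents_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "p": p,
    }


def _as_rna(base: str) -> str:
    return "U" if base in ("T", "U") else base


def _pair_label(mirna_base: str, target_base: str) -> str:
    pair = (_as_rna(mirna_base), _as_rna(target_base))
    if pair in _WC:
        return "WC"
    if pair in _WOBBLE:
        return "wobble"
    return "mismatch"


def seed_scan(target_seq: str, mirna_seq: str, target_name: str = "target",
              min_matches: int = 7, max_wobble: int = 1,
              exact_wobble: bool = False) -> list[SeedMatch]:
    """Scan a target mRNA (sense strand, 5'->3') for miRNA seed matches.

    Every target heptamer is paired antiparallel against miRNA positions
    2-8 (1-based from the miRNA 5' end): miRNA position 2 pairs with the
    3'-most base of the heptamer. Watson-Crick pairs are A:U and G:C;
    G:U is a wobble. A window is reported iff WC+wobble pairs >=
    ``min_matches`` and the wobble count is <= ``max_wobble`` (or exactly
    ``max_wobble`` with ``exact_wobble``).
    """
    if len(mirna_seq) < 8:
        raise ValueError("miRNA must be at least 8 nt for a 2-8 seed")
    target = target_seq.upper()
    seed = mirna_seq.upper()[1:8]  # positions 2..8, 5'->3'
    matches: list[SeedMatch] = []
    for i in range(len(target) - SEED_LEN + 1):
        window = target[i:i + SEED_LEN]
        # miRNA position 2+k pairs with target position i+6-k
        labels = tuple(_pair_label(seed[k], window[SEED_LEN - 1 - k]) for k in range(SEED_LEN))
        n_wc = labels.count("WC")
        n_wobble = labels.count("wobble")
        wobble_ok = n_wobble == max_wobble if exact_wobble else n_wobble <= max_wobble
        if n_wc + n_wobble >= min_matches and wobble_ok:
            matches.append(SeedMatch(target_name=target_name, start=i, end=i + SEED_LEN,
                                     pairing=labels, n_wc=n_wc, n_wobble=n_wobble))
    return matches


def apply_edits(target_seq: str, edit_positions) -> str:
    """Substitute G at edited positions (inosine is read as guanosine)."""
    seq = list(target_seq.upper())
    for pos in edit_positions:
        if not 0 <= pos < len(seq):
            raise ValueError(f"edit position {pos} outside sequence of length {len(seq)}")
        seq[pos] = "G"
    return "".join(seq)


def editing_effect_on_matches(target_seq: str, edit_positions, mirna_seq: str,
                              target_name: str = "target", min_matches: int = 7,
                              max_wobble: int = 1) -> list[dict]:
    """Per-edit-site effect of A-to-G substitution on seed matches.

    For each edited position, seed matches whose window overlaps the site
    are compared before and after substituting G at all edit positions;
    the verdict is created / destroyed / retained / unaffected.
    """
    target = target_seq.upper()
    for pos in edit_positions:
        if not 0 <= pos < len(target):
            raise ValueError(f"edit position {pos} outside sequence")
    edited = apply_edits(target, edit_positions)
    before = seed_scan(target, mirna_seq, target_name, min_matches, max_wobble)
    after = seed_scan(edited, mirna_seq, target_name, min_matches, max_wobble)
    out = []
    for pos in edit_positions:
        if target[pos] != "A":
            # edits are A-to-I; a non-A position is allowed but suspicious
            pass
        b = [m for m in before if m.start <= pos < m.end]
        a = [m for m in after if m.start <= pos < m.end]
        if not b and not a:
            verdict = "unaffected"
        elif b and not a:
            verdict = "destroyed"
        elif a and not b:
            verdict = "created"
        else:
            verdict = "retained"
        out.append({"position": pos, "matches_before": b, "matches_after": a,
                    "verdict": verdict})
    return out
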