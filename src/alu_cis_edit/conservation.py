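"""Conservation-window scoring around editing sites and the proximal/distal contrast.

For each non-clustered site the window is the site plus 15 flanking
nucleotides on each side (31 positions), trimmed to the host exon so that
only exonic bases are compared; per-base conservation scores (PhyloP- or
PhastCons-style) are averaged over covered positions. Sites within 1 kb of
the nearest edited Alu form the proximal group, the rest the distal group,
and the two mean-score distributions are compared with both a t-test and a
Mann-Whitney U-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ScoreTrack


@dataclass
class GroupingConfig:
    proximal_threshold: int = 1000  # inclusive: gap <= threshold is proximal
    min_coverage: int = 16  # covered positions required for a defined mean
    flank: int = 15

    def __post_init__(self) -> None:
        if min(self.proximal_threshold, self.min_coverage, self.flank) < 1:
            raise ValueError("all grouping parameters must be >= 1")


@dataclass
class ConservationWindow:
    site: object
    requested: list  # positions site-flank .. site+flank
    retained: list  # after exon trimming; always contains the site position
    n_covered: int = 0
    mean_score: float | None = None


def extract_window(site, flank: int, host_exons=None) -> ConservationWindow:
    """Window positions around a site, trimmed to the host exon set.

    ``host_exons`` is an iterable of exon intervals (all transcripts
    containing the site; their union is used). Without exons the full
    2*flank+1 window is kept.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    requested = list(range(site.pos - flank, site.pos + flank + 1))
    if host_exons is None:
        retained = [p for p in requested if p >= 0]
    else:
        exonic: set[int] = set()
        for e in host_exons:
            if e.chrom == site.chrom:
                exonic.update(range(max(e.start, site.pos - flank),
                                    min(e.end, site.pos + flank + 1)))
        retained = sorted(set(p for p in requested if p in exonic) | {site.pos})
        retained = [p for p in retained if p >= 0]
    return ConservationWindow(site=site, requested=requested, retained=retained)


def window_mean_score(window: ConservationWindow, track: ScoreTrack,
                      min_coverage: int = 16) -> ConservationWindow:
    """Fill in the mean over covered positions; undefined below min_coverage."""
    scores, mask = track.get_many(window.site.chrom, window.retained)
    window.n_covered = int(mask.sum())
    window.mean_score = float(scores[mask].mean()) if window.n_covered >= min_coverage else None
    return window


def split_proximal_distal(windows, distance_records, grouping: GroupingConfig):
    """Partition window means into proximal/distal groups by Alu distance.

    ``distance_records`` aligns with ``windows``; sites without a record
    or without a defined mean are excluded and tallied. Returns
    (proximal means, distal means, n_excluded).
    """
    proximal: list[float] = []
    distal: list[float] = []
    n_excluded = 0
    for w, rec in zip(windows, distance_records):
        if rec is None or w.mean_score is None:
            n_excluded += 1
            continue
        if rec.genomic_gap <= grouping.proximal_threshold:
            proximal.append(w.mean_score)
        else:
            distal.append(w.mean_score)
    return proximal, distal, n_excluded


def compare_groups(group_a, group_b, test: str = "t", hist_bin: float = 0.05) -> dict:
    """Two-sided comparison of two score groups plus a fixed-width histogram.

    ``test`` is 't' (Welch) or 'mann_whitney'. The histogram (bin width
    ``hist_bin`` on [0, 1]) is reported per group so an ultra-conserved
    mode in the top bin is visible; scores outside [0, 1] are tallied
    separately.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("group_a", a), ("group_b", b)):
        if len(g) < 2:
            raise ValueError(f"{name} has fewer than 2 observations")
    if test == "t":
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            statistic, p = 0.0, 1.0
        else:
            statistic, p = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney":
        statistic, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}; use 't' or 'mann_whitney'")
    edges = np.round(np.arange(0.0, 1.0 + hist_bin / 2, hist_bin), 10)
    return {
        "test": test,
        "statistic": float(statistic),
        "p": float(p),
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "histogram": {
            "edges": edges.tolist(),
            "counts_a": np.histogram(a, bins=edges)[0].tolist(),
            "counts_b": np.histogram(b, bins=edges)[0].tolist(),
            "out_of_range_a": int(((a < 0) | (a > 1)).sum()),
            "out_of_range_b": int(((b < 0) | (b > 1)).sum()),
        },
    }


def analyze_conservation(sites, distance_records, track, genes=None,
                         grouping: GroupingConfig | None = None) -> dict:
    """End-to-end window extraction, scoring, grouping and both tests."""
    grouping = grouping or GroupingConfig()
    exons_by_chrom: dict[str, list] = {}
    if genes:
        for g in genes:
            exons_by_chrom.setdefault(g.chrom, []).extend(g.exons)
    windows = []
    for s in sites:
        host = exons_by_chrom.get(s.chrom) if genes else None
        w = extract_window(s, grouping.flank, host)
        windows.append(window_mean_score(w, track, grouping.min_coverage))
    proximal, distal, n_excluded = split_proximal_distal(windows, distance_records, grouping)
    out = {
        "n_proximal": len(proximal),
        "n_distal": len(distal),
        "n_excluded": n_excluded,
    }
    if len(proximal) >= 2 and len(distal) >= 2:
        out["t"] = compare_groups(proximal, distal, test="t")
        out["mann_whitney"] = compare_groups(proximal, distal, test="mann_whitney")
    return out
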