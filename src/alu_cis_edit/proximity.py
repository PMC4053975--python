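"""Signed nearest-edited-Alu distances and the random-adenosine null.

Distances are counted in nucleotide steps between a site and the nearest
edge of the nearest edited Alu on the same chromosome: a site immediately
adjacent to an Alu edge has gap 1, so |d| >= 1 always. The sign is
transcript-oriented: positive means the Alu lies downstream of the site
(on a minus-strand gene, downstream is toward lower coordinates).
Equidistant up/downstream Alus break ties deterministically to downstream.
The null distribution uses the identical distance routine on randomly
sampled non-Alu adenosines, so any convention bias cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import build_interval_index
from .types import EditingSite


@dataclass
class DistanceRecord:
    site: EditingSite
    alu_name: str
    genomic_gap: int  # nucleotides to the nearest edited-Alu edge, >= 1
    signed_distance: int | None  # +gap Alu downstream, -gap upstream; None if strand unknown

    def __post_init__(self) -> None:
        if self.genomic_gap < 1:
            raise ValueError("genomic_gap must be >= 1 (site inside an Alu?)")
        if self.signed_distance is not None and abs(self.signed_distance) != self.genomic_gap:
            raise ValueError("|signed_distance| must equal genomic_gap")


@dataclass
class NullConfig:
    n_samples: int = 20_000
    seed: int = 0
    class_weights: dict | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.class_weights is not None:
            if any(w < 0 for w in self.class_weights.values()):
                raise ValueError("class weights must be >= 0")
            if all(w == 0 for w in self.class_weights.values()):
                raise ValueError("class weights must not all be zero")


@dataclass
class HistogramSpec:
    window: int = 20_000
    bin_width: int = 100
    signed: bool = False

    def __post_init__(self) -> None:
        if self.window % self.bin_width:
            raise ValueError("window must be divisible by bin_width")


class EditedAluIndex:
    """Per-chromosome sorted-edge index over edited Alu elements."""

    def __init__(self, alus, use_midpoint: bool = False):
        self.use_midpoint = use_midpoint
        edited = [a for a in alus if a.edited]
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cummax_end: dict[str, np.ndarray] = {}
        self._names_by_start: dict[str, list[str]] = {}
        self._names_by_end: dict[str, list[str]] = {}
        by_chrom: dict[str, list] = {}
        for a in edited:
            by_chrom.setdefault(a.interval.chrom, []).append(a)
        for chrom, group in by_chrom.items():
            if use_midpoint:
                # midpoint mode treats each Alu as the single base at its centre
                edges = [((a.interval.start + a.interval.end) // 2, a) for a in group]
                starts = sorted(edges, key=lambda t: (t[0], t[1].name))
                self._starts[chrom] = np.array([p for p, _ in starts], dtype=np.int64)
                self._names_by_start[chrom] = [a.name for _, a in starts]
                ends = sorted(((p + 1, a) for p, a in edges), key=lambda t: (t[0], t[1].name))
                self._ends[chrom] = np.array([p for p, _ in ends], dtype=np.int64)
                self._names_by_end[chrom] = [a.name for _, a in ends]
                self._cummax_end[chrom] = np.maximum.accumulate(self._starts[chrom] + 1)
            else:
                by_start = sorted(group, key=lambda a: (a.interval.start, a.name))
                self._starts[chrom] = np.array([a.interval.start for a in by_start], dtype=np.int64)
                self._names_by_start[chrom] = [a.name for a in by_start]
                self._cummax_end[chrom] = np.maximum.accumulate(
                    np.array([a.interval.end for a in by_start], dtype=np.int64)
                )
                by_end = sorted(group, key=lambda a: (a.interval.end, a.name))
                self._ends[chrom] = np.array([a.interval.end for a in by_end], dtype=np.int64)
                self._names_by_end[chrom] = [a.name for a in by_end]

    def chroms(self) -> set[str]:
        return set(self._starts)

    def gaps(self, chrom: str, positions) -> tuple[np.ndarray, np.ndarray, list, list]:
        """Vector gaps to nearest Alu right and left of each position.

        Returns (gap_right, gap_left, names_right, names_left); a gap of 0
        encodes 'no Alu on that side'. Positions inside an Alu raise.
        """
        positions = np.asarray(positions, dtype=np.int64)
        starts = self._starts.get(chrom)
        if starts is None:
            raise KeyError(chrom)
        ends = self._ends[chrom]
        idx_r = np.searchsorted(starts, positions, side="right")
        inside = (idx_r > 0) & (self._cummax_end[chrom][np.maximum(idx_r - 1, 0)] > positions)
        if np.any(inside):
            bad = positions[inside][0]
            raise ValueError(
                f"position {chrom}:{bad} lies inside an edited Alu; "
                "partition sites before computing distances"
            )
        gap_right = np.zeros(len(positions), dtype=np.int64)
        has_r = idx_r < len(starts)
        gap_right[has_r] = starts[np.minimum(idx_r, len(starts) - 1)][has_r] - positions[has_r]
        idx_l = np.searchsorted(ends, positions, side="right")
        gap_left = np.zeros(len(positions), dtype=np.int64)
        has_l = idx_l > 0
        gap_left[has_l] = positions[has_l] - ends[np.maximum(idx_l - 1, 0)][has_l] + 1
        names_r = [self._names_by_start[chrom][i] if ok else "" for i, ok in zip(idx_r, has_r)]
        names_l = [self._names_by_end[chrom][i - 1] if ok else "" for i, ok in zip(idx_l, has_l)]
        return gap_right, gap_left, names_r, names_l


def nearest_edited_alu(site, alu_index: EditedAluIndex, gene_strand: str | None = None):
    """Distance record for one site, or None when no edited Alu shares the chromosome.

    ``gene_strand`` is the host gene's strand (transcript orientation);
    when None, the site's own strand field is used; '.' leaves the signed
    distance undefined while keeping the unsigned gap.
    """
    if site.chrom not in alu_index.chroms():
        return None
    gap_r, gap_l, names_r, names_l = alu_index.gaps(site.chrom, [site.pos])
    return _combine(site, gene_strand, int(gap_r[0]), int(gap_l[0]), names_r[0], names_l[0])


def _combine(site, gene_strand, gap_right, gap_left, name_right, name_left):
    strand = gene_strand if gene_strand is not None else site.strand
    if strand == "+":
        gap_down, name_down, gap_up, name_up = gap_right, name_right, gap_left, name_left
    elif strand == "-":
        gap_down, name_down, gap_up, name_up = gap_left, name_left, gap_right, name_right
    else:
        # unresolvable orientation: keep the unsigned nearest gap only
        candidates = [(g, n) for g, n in ((gap_right, name_right), (gap_left, name_left)) if g > 0]
        if not candidates:
            return None
        gap, name = min(candidates)
        return DistanceRecord(site=site, alu_name=name, genomic_gap=gap, signed_distance=None)
    if gap_down == 0 and gap_up == 0:
        return None
    if gap_up == 0 or (gap_down != 0 and gap_down <= gap_up):  # tie -> downstream
        return DistanceRecord(site=site, alu_name=name_down, genomic_gap=gap_down,
                              signed_distance=+gap_down)
    return DistanceRecord(site=site, alu_name=name_up, genomic_gap=gap_up,
                          signed_distance=-gap_up)


def resolve_gene_strands(sites, genes) -> list:
    """Host-gene strand per site (gene-span containment); None outside genes."""
    from .types import GenomicInterval

    spans = build_interval_index(
        [GenomicInterval(g.chrom, g.span[0], g.span[1], g.strand, g.gene_id) for g in genes]
    )
    out = []
    for s in sites:
        tree = spans.get(s.chrom)
        hits = tree[s.pos] if tree is not None else set()
        out.append(genes[min(h.data for h in hits)].strand if hits else None)
    return out


def compute_distance_records(sites, alu_index: EditedAluIndex, genes=None):
    """Distance records for many sites; entries are None off-chromosome.

    With gene models supplied, orientation uses the host gene's strand;
    sites outside every gene fall back to their own strand field.
    """
    strand_of = resolve_gene_strands(sites, genes) if genes else [None] * len(sites)

    records: list[DistanceRecord | None] = [None] * len(sites)
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        if chrom not in alu_index.chroms():
            continue
        positions = [sites[i].pos for i in idxs]
        gap_r, gap_l, names_r, names_l = alu_index.gaps(chrom, positions)
        for j, i in enumerate(idxs):
            records[i] = _combine(sites[i], strand_of[i], int(gap_r[j]), int(gap_l[j]),
                                  names_r[j], names_l[j])
    return records


def sample_random_adenosines(pool, config: NullConfig):
    """Sample candidate adenosine positions without replacement.

    ``pool`` is a sequence of objects with a ``region`` attribute (or
    plain positions when no class weights are used). With class weights,
    each position's selection probability is proportional to its region
    class's weight. Deterministic for a fixed seed.
    """
    n = len(pool)
    if config.n_samples > n:
        raise ValueError(f"requested {config.n_samples} samples from a pool of {n}")
    rng = np.random.default_rng(config.seed)
    if config.class_weights:
        weights = np.array(
            [config.class_weights.get(getattr(p, "region", "unknown"), 0.0) for p in pool],
            dtype=float,
        )
        total = weights.sum()
        if total <= 0:
            raise ValueError("class weights give zero total probability over the pool")
        idx = rng.choice(n, size=config.n_samples, replace=False, p=weights / total)
    else:
        idx = rng.choice(n, size=config.n_samples, replace=False)
    return [pool[i] for i in idx]


@dataclass
class HistogramResult:
    table: pd.DataFrame  # bin_low, bin_high (both inclusive, nt), count, proportion
    n_total: int
    n_excluded: int


def distance_histogram(records, spec: HistogramSpec) -> HistogramResult:
    """Bin distances into fixed-width bins inside the window.

    Unsigned mode bins |d| over [1, window]; signed mode bins d over
    [-window, window] (d = 0 cannot occur). Distances beyond the window
    are excluded from the bins but counted.
    """
    if spec.signed:
        values = np.array([r.signed_distance for r in records if r.signed_distance is not None],
                          dtype=np.int64)
    else:
        values = np.array([r.genomic_gap for r in records], dtype=np.int64)
    n_total = len(values)
    inside = np.abs(values) <= spec.window
    vals = values[inside]
    w = spec.bin_width
    k = spec.window // w
    if spec.signed:
        idx = np.where(vals > 0, k + (vals - 1) // w, k - 1 - (-vals - 1) // w)
        lows = np.concatenate([-(np.arange(k, 0, -1) * w), np.arange(k) * w + 1])
        highs = np.concatenate([-(np.arange(k, 0, -1) * w) + w - 1, (np.arange(k) + 1) * w])
        nbins = 2 * k
    else:
        idx = (vals - 1) // w
        lows = np.arange(k) * w + 1
        highs = (np.arange(k) + 1) * w
        nbins = k
    counts = np.bincount(idx, minlength=nbins)
    total_in = counts.sum()
    table = pd.DataFrame({
        "bin_low": lows,
        "bin_high": highs,
        "count": counts,
        "proportion": counts / total_in if total_in else np.zeros(nbins),
    })
    return HistogramResult(table=table, n_total=n_total, n_excluded=int(n_total - total_in))


def orientation_test(records, max_distance: int = 2000) -> dict:
    """Exact binomial test of the downstream/upstream split within a window.

    Only records with a resolvable orientation and gap <= ``max_distance``
    are eligible; the two-sided test is against an even 0.5 split.
    """
    eligible = [r for r in records
                if r is not None and r.signed_distance is not None
                and r.genomic_gap <= max_distance]
    if not eligible:
        raise ValueError(f"no records with orientation within {max_distance} nt")
    n_down = sum(1 for r in eligible if r.signed_distance > 0)
    n_up = len(eligible) - n_down
    res = stats.binomtest(n_down, n_down + n_up, 0.5, alternative="two-sided")
    return {
        "n_down": n_down,
        "n_up": n_up,
        "fraction_down": n_down / (n_down + n_up),
        "p_value": float(res.pvalue),
    }


def compare_distance_distributions(obs_distances, null_distances, welch: bool = True) -> dict:
    """Two-sided two-sample t-test on unsigned distances (Welch by default)."""
    obs = np.asarray(obs_distances, dtype=float)
    null = np.asarray(null_distances, dtype=float)
    if len(obs) < 2 or len(null) < 2:
        raise ValueError("both samples need size >= 2")
    if obs.std() == 0 and null.std() == 0:
        equal = obs.mean() == null.mean()
        return {"t": 0.0, "p": 1.0 if equal else 0.0,
                "mean_obs": float(obs.mean()), "mean_null": float(null.mean())}
    t, p = stats.ttest_ind(obs, null, equal_var=not welch)
    return {"t": float(t), "p": float(p),
            "mean_obs": float(obs.mean()), "mean_null": float(null.mean())}
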