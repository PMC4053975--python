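"""Synthetic genomes, editing sites, conservation tracks and peak tables.

The generator emulates the statistical structure the analysis assumes:
genes containing inverted Alu pairs, a subset of Alus edited (each edited
Alu also carries in-Alu editing sites, so the partitioning stage derives
the edited flag the same way it would on real data), non-Alu sites placed
by a two-component mixture — uniform background, plus a proximity
mechanism that puts a site at an Exponential(lambda) distance from a
random edited Alu with a configurable downstream-orientation bias — and
per-base conservation tracks whose proximal/distal window means differ by
a configurable effect, with an optional ultra-conserved component.

All randomness flows from one master seed through fixed per-component
substreams, so equal configs give byte-identical outputs.
"""

from __future__ import annotations

import bisect
import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as aio
from .types import AluElement, EditingSite, GeneModel, GenomicInterval, ScoreTrack


class GeometryError(ValueError):
    """The requested genome geometry does not fit; raised before any output."""


@dataclass
class SyntheticConfig:
    # genome geometry
    n_chroms: int = 2
    chrom_length: int = 25_000_000
    n_genes: int = 100  # per chromosome
    exons_per_gene: int = 5
    exon_length: int = 600
    alu_length: int = 300
    n_alu_pairs_per_gene: int = 5
    pair_gap: int = 60  # nt between the two Alus of a pair
    inverted_pair_fraction: float = 1.0
    edited_alu_fraction: float = 0.5
    n_alu_sites_per_edited: int = 2  # in-Alu sites marking an Alu as edited
    # non-Alu site placement
    n_sites: int = 2000
    pi: float = 0.6  # proportion placed by the proximity mechanism
    lam: float = 400.0  # exponential decay scale of |distance| (nt)
    p_down: float = 0.56  # probability the recruiting Alu is downstream of the site
    n_injected_clusters: int = 0
    cluster_sites: int = 4
    cluster_gap: int = 30  # consecutive spacing inside an injected cluster
    # conservation track
    cons_mu_proximal: float = 0.4
    cons_mu_distal: float = 0.6
    cons_sd: float = 0.25
    ultra_conserved_fraction: float = 0.0  # fraction of distal windows pinned at 1.0
    cons_flank: int = 15
    cons_proximal_threshold: int = 1000
    # random-adenosine pool
    pool_size: int = 5000
    # sampling control
    seed: int = 0
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        for name in ("pi", "p_down", "inverted_pair_fraction", "edited_alu_fraction",
                     "ultra_conserved_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_length", "n_genes", "exons_per_gene",
                     "alu_length", "n_sites", "pool_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


@dataclass
class SimulatedGenome:
    genes: list
    alus: list
    alu_host: list = field(default_factory=list)  # gene index per Alu
    alu_block: list = field(default_factory=list)  # enclosing pair block (start, end) per Alu

    def edited_alus(self):
        return [a for a in self.alus if a.edited]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def simulate_genome(config: SyntheticConfig) -> SimulatedGenome:
    """Place genes with evenly spaced exons and intronic Alu pairs.

    Inverted pairs get opposite strands; each Alu is independently flagged
    edited with probability ``edited_alu_fraction``. Infeasible geometry
    raises :class:`GeometryError` before any output.
    """
    rng = _rng(config, 11)
    slot = config.chrom_length // config.n_genes
    margin = max(slot // 10, 1)
    span = slot - 2 * margin
    block = 2 * config.alu_length + config.pair_gap
    need = config.exons_per_gene * config.exon_length + config.n_alu_pairs_per_gene * block
    if span <= 0 or need > span // 2:
        raise GeometryError(
            f"gene span {span} nt cannot hold {config.exons_per_gene} exons and "
            f"{config.n_alu_pairs_per_gene} Alu pairs (need ~{2 * need} nt)"
        )
    genes: list[GeneModel] = []
    alus: list[AluElement] = []
    alu_host: list[int] = []
    alu_block: list[tuple] = []
    families = np.array(["AluSx", "AluY", "AluJb"])
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for gi in range(config.n_genes):
            g_start = gi * slot + margin
            g_end = (gi + 1) * slot - margin
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{chrom}_gene{gi}"
            exon_starts = np.linspace(g_start, g_end - config.exon_length,
                                      config.exons_per_gene).astype(int)
            exons = [GenomicInterval(chrom, int(s), int(s) + config.exon_length,
                                     strand, gene_id) for s in exon_starts]
            gene_idx = len(genes)
            genes.append(GeneModel(gene_id=gene_id, strand=strand, exons=exons))
            placed: list[tuple[int, int]] = [(e.start, e.end) for e in exons]
            for pair in range(config.n_alu_pairs_per_gene):
                start = _place_block(rng, g_start, g_end, block, placed, config.max_redraws)
                placed.append((start, start + block))
                inverted = rng.random() < config.inverted_pair_fraction
                strands = (strand, _flip(strand) if inverted else strand)
                for k, s0 in enumerate((start, start + config.alu_length + config.pair_gap)):
                    name = f"{gene_id}_alu{pair}{'ab'[k]}"
                    iv = GenomicInterval(chrom, s0, s0 + config.alu_length, strands[k], name)
                    alus.append(AluElement(
                        interval=iv,
                        family=str(rng.choice(families)),
                        edited=bool(rng.random() < config.edited_alu_fraction),
                    ))
                    alu_host.append(gene_idx)
                    alu_block.append((start, start + block))
    return SimulatedGenome(genes=genes, alus=alus, alu_host=alu_host, alu_block=alu_block)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _place_block(rng, g_start, g_end, block, placed, max_tries) -> int:
    for _ in range(max_tries):
        s = int(rng.integers(g_start, g_end - block))
        if all(s + block <= a or s >= b for a, b in placed):
            return s
    raise GeometryError("could not place an Alu pair without overlap; geometry too cramped")


class _AluLookup:
    """Point-in-any-Alu test over sorted starts with cumulative max ends."""

    def __init__(self, alus):
        self._starts: dict[str, list[int]] = {}
        self._cummax: dict[str, list[int]] = {}
        by_chrom: dict[str, list] = {}
        for a in alus:
            by_chrom.setdefault(a.interval.chrom, []).append(a.interval)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            self._starts[chrom] = [iv.start for iv in ivs]
            cm, top = [], 0
            for iv in ivs:
                top = max(top, iv.end)
                cm.append(top)
            self._cummax[chrom] = cm

    def __contains__(self, key) -> bool:
        chrom, pos = key
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos)
        return i > 0 and self._cummax[chrom][i - 1] > pos


def _assign_region(rng, exonic: bool) -> str:
    if not exonic:
        return "intron"
    return str(rng.choice(["utr3", "missense", "synonymous", "utr5"],
                          p=[0.35, 0.3, 0.2, 0.15]))


class _ExonLookup:
    def __init__(self, genes):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        by_chrom: dict[str, list] = {}
        for g in genes:
            for e in g.exons:
                by_chrom.setdefault(e.chrom, []).append(e)
        for chrom, exons in by_chrom.items():
            exons.sort(key=lambda e: e.start)
            self._starts[chrom] = [e.start for e in exons]
            self._ends[chrom] = [e.end for e in exons]

    def __contains__(self, key) -> bool:
        chrom, pos = key
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos)
        return i > 0 and self._ends[chrom][i - 1] > pos


def simulate_sites(config: SyntheticConfig, genome: SimulatedGenome):
    """Generate the full site table: in-Alu, mechanism, background, clusters.

    Returns (sites, truth) where ``truth`` records ground-truth placement
    labels and counts; each site's ``source`` field carries its label
    ('alu', 'mechanism', 'background', 'cluster') so labels survive a
    round-trip through the site-table format.
    """
    rng = _rng(config, 22)
    in_alu = _AluLookup(genome.alus)
    exonic = _ExonLookup(genome.genes)
    edited = [
        (a, genome.genes[h], blk)
        for a, h, blk in zip(genome.alus, genome.alu_host, genome.alu_block)
        if a.edited
    ]
    if config.pi > 0 and config.n_sites > 0 and not edited:
        raise ValueError("pi > 0 requires at least one edited Alu")
    used: set[tuple] = set()
    sites: list[EditingSite] = []

    def add(chrom, pos, strand, label, region=None):
        used.add((chrom, pos))
        sites.append(EditingSite(
            chrom=chrom, pos=pos, strand=strand,
            region=region if region is not None else _assign_region(rng, (chrom, pos) in exonic),
            tissue_derived=True, on_refseq=True, source=label,
        ))

    # in-Alu sites give the partitioning stage direct evidence of editing
    for alu, gene, _blk in edited:
        iv = alu.interval
        n = min(config.n_alu_sites_per_edited, len(iv))
        for pos in rng.choice(len(iv), size=n, replace=False):
            p = iv.start + int(pos)
            if (iv.chrom, p) not in used:
                add(iv.chrom, p, gene.strand, "alu", region="intron")

    # non-Alu sites: proximity mechanism vs uniform background
    gene_spans = [(g.chrom, *g.span, g.strand) for g in genome.genes]
    weights = np.array([e - s for _, s, e, _ in gene_spans], dtype=float)
    weights /= weights.sum()
    n_mech = 0
    for _ in range(config.n_sites):
        if rng.random() < config.pi:
            chrom, pos, strand = _draw_mechanism(rng, config, edited, in_alu, used)
            n_mech += 1
            add(chrom, pos, strand, "mechanism")
        else:
            chrom, pos, strand = _draw_background(rng, config, gene_spans, weights, in_alu, used)
            add(chrom, pos, strand, "background")

    # injected clusters
    cluster_positions: list[list] = []
    span_needed = (config.cluster_sites - 1) * config.cluster_gap
    for _ in range(config.n_injected_clusters):
        for _try in range(config.max_redraws):
            gidx = rng.choice(len(gene_spans), p=weights)
            chrom, g_start, g_end, strand = gene_spans[gidx]
            start = int(rng.integers(g_start, g_end - span_needed))
            members = [start + k * config.cluster_gap for k in range(config.cluster_sites)]
            if all((chrom, m) not in in_alu and (chrom, m) not in used for m in members):
                for m in members:
                    add(chrom, m, strand, "cluster")
                cluster_positions.append([chrom, members])
                break
        else:
            raise GeometryError("could not place an injected cluster")

    sites.sort(key=lambda s: (s.chrom, s.pos))
    truth = {
        "n_alu_sites": sum(1 for s in sites if s.source == "alu"),
        "n_mechanism": n_mech,
        "n_background": sum(1 for s in sites if s.source == "background"),
        "n_cluster": sum(1 for s in sites if s.source == "cluster"),
        "n_edited_alus": len(edited),
        "cluster_positions": cluster_positions,
    }
    return sites, truth


def _draw_mechanism(rng, config, edited, in_alu, used):
    # The site is offset from the recruiting Alu's pair envelope, not the
    # Alu itself: placing it off the bare Alu would reject every draw that
    # lands inside the pair partner, which skews the orientation bias.
    alu, gene, (blk_start, blk_end) = edited[rng.integers(len(edited))]
    chrom = alu.interval.chrom
    g_start, g_end = gene.span
    for _ in range(config.max_redraws):
        d = max(1, math.ceil(rng.exponential(config.lam)))
        alu_downstream = rng.random() < config.p_down
        # positive orientation: the Alu sits downstream of the site in
        # transcript coordinates (lower coordinates on a minus-strand gene)
        left = alu_downstream if gene.strand == "+" else not alu_downstream
        pos = blk_start - d if left else blk_end - 1 + d
        if g_start <= pos < g_end and (chrom, pos) not in in_alu and (chrom, pos) not in used:
            return chrom, pos, gene.strand
    raise GeometryError("mechanism site placement exceeded the redraw cap")


def _draw_background(rng, config, gene_spans, weights, in_alu, used):
    for _ in range(config.max_redraws):
        gidx = rng.choice(len(gene_spans), p=weights)
        chrom, g_start, g_end, strand = gene_spans[gidx]
        pos = int(rng.integers(g_start, g_end))
        if (chrom, pos) not in in_alu and (chrom, pos) not in used:
            return chrom, pos, strand
    raise GeometryError("background site placement exceeded the redraw cap")


def simulate_pool(config: SyntheticConfig, genome: SimulatedGenome):
    """Candidate-adenosine pool: uniform gene-body positions outside Alus."""
    rng = _rng(config, 33)
    in_alu = _AluLookup(genome.alus)
    exonic = _ExonLookup(genome.genes)
    gene_spans = [(g.chrom, *g.span, g.strand) for g in genome.genes]
    weights = np.array([e - s for _, s, e, _ in gene_spans], dtype=float)
    weights /= weights.sum()
    used: set[tuple] = set()
    pool: list[EditingSite] = []
    for _ in range(config.pool_size):
        for _try in range(config.max_redraws):
            gidx = rng.choice(len(gene_spans), p=weights)
            chrom, g_start, g_end, strand = gene_spans[gidx]
            pos = int(rng.integers(g_start, g_end))
            if (chrom, pos) not in in_alu and (chrom, pos) not in used:
                used.add((chrom, pos))
                pool.append(EditingSite(
                    chrom=chrom, pos=pos, strand=strand,
                    region=_assign_region(rng, (chrom, pos) in exonic),
                    source="pool",
                ))
                break
        else:
            raise GeometryError("pool sampling exceeded the redraw cap")
    pool.sort(key=lambda s: (s.chrom, s.pos))
    return pool


def simulate_conservation(config: SyntheticConfig, sites, distance_records) -> ScoreTrack:
    """Per-base conservation scores over the window around every site.

    Windows around proximal sites (gap <= ``cons_proximal_threshold``)
    draw from a [0,1]-truncated Normal(mu_proximal, sd); distal windows
    from Normal(mu_distal, sd); a fraction of distal windows is pinned at
    1.0 (the ultra-conserved component). Positions outside windows stay
    uncovered. When two windows overlap, the first writer wins.
    """
    rng = _rng(config, 44)
    per_chrom: dict[str, dict[int, float]] = {}
    width = 2 * config.cons_flank + 1

    def truncated(mu, n):
        a, b = (0.0 - mu) / config.cons_sd, (1.0 - mu) / config.cons_sd
        return stats.truncnorm.rvs(a, b, loc=mu, scale=config.cons_sd, size=n, random_state=rng)

    for site, rec in zip(sites, distance_records):
        if rec is None:
            continue
        proximal = rec.genomic_gap <= config.cons_proximal_threshold
        if proximal:
            scores = truncated(config.cons_mu_proximal, width)
        elif rng.random() < config.ultra_conserved_fraction:
            scores = np.ones(width)
        else:
            scores = truncated(config.cons_mu_distal, width)
        mapping = per_chrom.setdefault(site.chrom, {})
        for off, sc in zip(range(-config.cons_flank, config.cons_flank + 1), scores):
            pos = site.pos + off
            if pos >= 0 and pos not in mapping:
                mapping[pos] = float(sc)
    return ScoreTrack.from_positions(per_chrom)


def simulate_peak_table(true_percents, noise_sd: float = 2.0, seed: int = 0,
                        total_height: float = 1000.0) -> pd.DataFrame:
    """Chromatogram peak-height rows whose G/(A+G) ratio encodes the truth.

    Gaussian noise (``noise_sd`` percentage points, clipped to [0, 100])
    perturbs each true editing percentage; C and T carry small nuisance
    heights.
    """
    rng = np.random.default_rng([seed % (2**31), 55])
    rows = []
    for truth in true_percents:
        if not 0 <= truth <= 100:
            raise ValueError(f"true percent {truth} outside [0, 100]")
        noisy = float(np.clip(truth + rng.normal(0.0, noise_sd), 0.0, 100.0)) \
            if noise_sd > 0 else float(truth)
        g = noisy / 100.0 * total_height
        rows.append({
            "A": total_height - g, "C": float(rng.uniform(5, 30)),
            "G": g, "T": float(rng.uniform(5, 30)),
            "true_percent": float(truth),
        })
    return pd.DataFrame(rows, columns=["A", "C", "G", "T", "true_percent"])


def write_outputs(outdir, config: SyntheticConfig, genome: SimulatedGenome,
                  sites, truth, pool, track: ScoreTrack | None = None,
                  peaks: pd.DataFrame | None = None) -> dict:
    """Write every generated artifact in the pipeline's input formats."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genes": os.path.join(outdir, "genes.bed"),
        "alus": os.path.join(outdir, "alus.bed"),
        "edited_alus": os.path.join(outdir, "edited_alus.bed"),
        "sites": os.path.join(outdir, "sites.tsv"),
        "pool": os.path.join(outdir, "pool.bed"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    aio.write_bed_intervals([e for g in genome.genes for e in g.exons], paths["genes"])
    aio.write_bed_intervals([a.interval for a in genome.alus], paths["alus"])
    aio.write_bed_intervals([a.interval for a in genome.alus if a.edited], paths["edited_alus"])
    aio.write_site_table(sites, paths["sites"])
    aio.write_bed_intervals(
        [GenomicInterval(p.chrom, p.pos, p.pos + 1, p.strand, p.region) for p in pool],
        paths["pool"],
    )
    if track is not None:
        paths["conservation"] = os.path.join(outdir, "conservation.bedgraph")
        aio.write_score_track(track, paths["conservation"])
    if peaks is not None:
        paths["peaks"] = os.path.join(outdir, "peaks.tsv")
        peaks.to_csv(paths["peaks"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({"config": asdict(config), "truth": truth}, fh, indent=1)
    return paths
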