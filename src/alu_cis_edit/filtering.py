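"""Inclusion filters, Alu/non-Alu partitioning, and editing-cluster removal.

Clustered editing (many edited adenosines in a short stretch) marks long
stable duplexes; removing clusters isolates the site-selective events the
proximity analysis is about. A cluster is a maximal chain of sites with
consecutive gaps <= ``cluster_max_gap`` that has at least
``cluster_min_sites`` members and spans at least ``cluster_min_span``
nucleotides from first to last site.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .types import AluElement, EditingSite


@dataclass
class FilterConfig:
    require_refseq: bool = True
    require_tissue: bool = True
    cluster_max_gap: int = 40
    cluster_min_sites: int = 3
    cluster_min_span: int = 70
    span_inclusive: bool = True  # span = last - first + 1 (inclusive of both end sites)
    cluster_per_strand: bool = True

    def __post_init__(self) -> None:
        if self.cluster_max_gap < 1:
            raise ValueError("cluster_max_gap must be >= 1")
        if self.cluster_min_sites < 2:
            raise ValueError("cluster_min_sites must be >= 2")
        if self.cluster_min_span < 1:
            raise ValueError("cluster_min_span must be >= 1")


@dataclass
class Cluster:
    chrom: str
    group: str  # strand-group key ('+', '-', or '.' when strand-agnostic)
    positions: list = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.positions[-1] - self.positions[0] + 1

    def __len__(self) -> int:
        return len(self.positions)


def build_interval_index(intervals) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for point-containment queries."""
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def apply_inclusion_filters(sites, genes=None, config: FilterConfig | None = None):
    """Keep sites passing the enabled provenance filters; collapse duplicates.

    When a gene model is supplied, ``on_refseq`` is recomputed as overlap
    with the transcript extent (first exon start to last exon end; editing
    is a pre-mRNA event, so intronic positions count). Duplicate
    coordinates (same chrom, pos, strand) collapse to one record with
    sources concatenated by ';'.
    """
    from .types import GenomicInterval

    config = config or FilterConfig()
    if genes:
        span_index = build_interval_index(
            [GenomicInterval(g.chrom, g.span[0], g.span[1], g.strand, g.gene_id)
             for g in genes]
        )
        for s in sites:
            tree = span_index.get(s.chrom)
            s.on_refseq = bool(tree is not None and tree[s.pos])
    kept: "OrderedDict[tuple, EditingSite]" = OrderedDict()
    for s in sites:
        if config.require_tissue and not s.tissue_derived:
            continue
        if config.require_refseq and not s.on_refseq:
            continue
        prev = kept.get(s.key)
        if prev is None:
            kept[s.key] = EditingSite(**{k: getattr(s, k) for k in (
                "chrom", "pos", "strand", "region", "tissue_derived",
                "on_refseq", "source", "in_alu")})
        else:
            labels = [x for x in (prev.source, s.source) if x]
            if s.source and s.source not in prev.source.split(";"):
                prev.source = ";".join(labels)
    return list(kept.values())


def partition_and_flag(sites, alus):
    """Split sites into (non_alu, alu) and flag Alus containing a site as edited.

    A site is in-Alu iff its position lies within at least one Alu interval
    (half-open); an Alu is edited iff at least one site lies within it.
    """
    trees = build_interval_index([a.interval for a in alus])
    non_alu: list[EditingSite] = []
    in_alu: list[EditingSite] = []
    edited_idx: set[int] = set()
    for s in sites:
        tree = trees.get(s.chrom)
        hits = tree[s.pos] if tree is not None else set()
        s.in_alu = bool(hits)
        (in_alu if s.in_alu else non_alu).append(s)
        edited_idx.update(h.data for h in hits)
    flagged = [
        AluElement(interval=a.interval, family=a.family, edited=(i in edited_idx or a.edited))
        for i, a in enumerate(alus)
    ]
    return non_alu, in_alu, flagged


def _group_key(site: EditingSite, per_strand: bool) -> tuple[str, str]:
    return (site.chrom, site.strand if per_strand else ".")


def detect_clusters(non_alu_sites, config: FilterConfig | None = None) -> list[Cluster]:
    """Find maximal consecutive-gap chains passing both cluster thresholds.

    Sites are grouped per (chrom, strand) when strand is known; within a
    group, sorted positions are chained while the gap to the previous site
    is <= ``cluster_max_gap``. A maximal chain is reported iff it has
    >= ``cluster_min_sites`` members and its first-to-last span passes
    ``cluster_min_span``.
    """
    config = config or FilterConfig()
    groups: dict[tuple, list[int]] = {}
    for s in non_alu_sites:
        groups.setdefault(_group_key(s, config.cluster_per_strand), []).append(s.pos)
    clusters: list[Cluster] = []
    for (chrom, grp), positions in sorted(groups.items()):
        positions = sorted(set(positions))
        chain = [positions[0]] if positions else []
        for pos in positions[1:]:
            if pos - chain[-1] <= config.cluster_max_gap:
                chain.append(pos)
            else:
                _maybe_report(clusters, chrom, grp, chain, config)
                chain = [pos]
        if chain:
            _maybe_report(clusters, chrom, grp, chain, config)
    return clusters


def _maybe_report(clusters, chrom, grp, chain, config) -> None:
    span = chain[-1] - chain[0] + (1 if config.span_inclusive else 0)
    if len(chain) >= config.cluster_min_sites and span >= config.cluster_min_span:
        clusters.append(Cluster(chrom=chrom, group=grp, positions=list(chain)))


def remove_clustered(non_alu_sites, clusters, per_strand: bool = True):
    """Drop cluster members from the site list.

    Returns (retained sites, removed count). A cluster position absent from
    the site set is a consistency error: clusters must come from
    :func:`detect_clusters` on the same sites.
    """
    member_keys: set[tuple] = set()
    for c in clusters:
        for pos in c.positions:
            member_keys.add((c.chrom, c.group, pos))
    site_keys = {(s.chrom, s.strand if per_strand else ".", s.pos) for s in non_alu_sites}
    orphans = member_keys - site_keys
    if orphans:
        raise ValueError(f"cluster positions absent from site set: {sorted(orphans)[:5]}")
    retained = [
        s for s in non_alu_sites
        if (s.chrom, s.strand if per_strand else ".", s.pos) not in member_keys
    ]
    return retained, len(non_alu_sites) - len(retained)
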