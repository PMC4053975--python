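"""Readers and writers for the genomic formats the pipeline touches.

Formats: BED3/BED6 intervals, exon-level BED6 or BED12 gene models,
bedGraph / fixed-step WIG score tracks, FASTA sequences, and headered TSV
editing-site tables. Everything is parsed into 0-based half-open
coordinates; a dialect flag converts 1-based site tables on read.
"""

from __future__ import annotations

import re
from collections import OrderedDict

import pandas as pd
from Bio import SeqIO

from .types import AluElement, EditingSite, GeneModel, GenomicInterval, ScoreTrack


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


SITE_COLUMNS = ["chrom", "pos", "strand", "region", "tissue_derived", "on_refseq", "source"]

_VALID_SEQ = re.compile(r"^[ACGTUN]+$")


def _normalize_chrom(chrom: str, normalize: bool) -> str:
    if not normalize:
        return chrom
    return chrom if chrom.startswith("chr") else "chr" + chrom


def read_bed_intervals(path, normalize_chrom: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED6 into a list of intervals, preserving file order.

    BED is 0-based half-open; coordinates are kept unchanged. Lines with
    non-integer coordinates or start >= end raise :class:`ParseError`
    naming the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 tab-separated fields")
            chrom = _normalize_chrom(fields[0], normalize_chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed_intervals(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_alus(path, normalize_chrom: bool = False) -> list[AluElement]:
    """Read a RepeatMasker-style BED6 of Alu elements (name = family)."""
    return [
        AluElement(interval=iv, family=iv.name)
        for iv in read_bed_intervals(path, normalize_chrom)
    ]


def read_gene_models(path, normalize_chrom: bool = False) -> list[GeneModel]:
    """Read gene models from BED12 or exon-level BED6.

    BED12 rows (12 columns) expand blocks into exons; BED6 rows are exons
    grouped by name. A gene needs a usable +/- strand.
    """
    genes: "OrderedDict[str, GeneModel]" = OrderedDict()
    exons_by_gene: "OrderedDict[str, list]" = OrderedDict()
    strands: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 12:
                chrom = _normalize_chrom(fields[0], normalize_chrom)
                start = int(fields[1])
                name, strand = fields[3], fields[5]
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != len(offsets):
                    raise ParseError(f"{path}:{lineno}: blockSizes/blockStarts mismatch")
                exons = [
                    GenomicInterval(chrom, start + off, start + off + size, strand, name)
                    for off, size in zip(offsets, sizes)
                ]
                genes[name] = GeneModel(gene_id=name, strand=strand, exons=exons)
            elif len(fields) >= 6:
                iv = read_bed_line_interval(fields, path, lineno, normalize_chrom)
                exons_by_gene.setdefault(iv.name, []).append(iv)
                strands[iv.name] = iv.strand
            else:
                raise ParseError(f"{path}:{lineno}: gene models need BED6 or BED12")
    for name, exons in exons_by_gene.items():
        genes[name] = GeneModel(gene_id=name, strand=strands[name], exons=exons)
    return list(genes.values())


def read_bed_line_interval(fields, path, lineno, normalize_chrom=False) -> GenomicInterval:
    try:
        return GenomicInterval(
            _normalize_chrom(fields[0], normalize_chrom),
            int(fields[1]),
            int(fields[2]),
            fields[5] if len(fields) > 5 else ".",
            fields[3] if len(fields) > 3 else "",
        )
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_score_track(path, normalize_chrom: bool = False) -> ScoreTrack:
    """Read a bedGraph (4-column) or fixed-step WIG file into a ScoreTrack.

    Two source records covering the same position raise :class:`ParseError`
    (each base carries at most one score). An empty file yields a track
    where every query is undefined.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    wig_chrom = None
    wig_pos = wig_step = wig_span = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(kv.split("=") for kv in line.split()[1:])
                wig_chrom = _normalize_chrom(attrs["chrom"], normalize_chrom)
                wig_pos = int(attrs["start"]) - 1  # WIG declares 1-based starts
                wig_step = int(attrs.get("step", 1))
                wig_span = int(attrs.get("span", 1))
                continue
            if line.startswith("variableStep"):
                raise ParseError(f"{path}:{lineno}: variableStep WIG is not supported")
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1 and wig_chrom is not None:
                score = float(fields[0])
                _add_run(per_chrom, wig_chrom, wig_pos, wig_pos + wig_span, score, path, lineno)
                wig_pos += wig_step
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = _normalize_chrom(fields[0], normalize_chrom)
            try:
                start, end, score = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad bedGraph record") from exc
            if not 0 <= start < end:
                raise ParseError(f"{path}:{lineno}: require 0 <= start < end")
            _add_run(per_chrom, chrom, start, end, score, path, lineno)
    return ScoreTrack.from_positions(per_chrom)


def _add_run(per_chrom, chrom, start, end, score, path, lineno) -> None:
    mapping = per_chrom.setdefault(chrom, {})
    for pos in range(start, end):
        if pos in mapping:
            raise ParseError(f"{path}:{lineno}: position {chrom}:{pos} scored twice")
        mapping[pos] = score


def write_score_track(track: ScoreTrack, path) -> None:
    """Write a ScoreTrack as bedGraph, merging equal-score runs."""
    with open(path, "w") as fh:
        for chrom, start, end, score in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into name -> uppercase sequence over {A,C,G,T,U,N}.

    Duplicate record names and non-IUPAC characters are errors; U and T
    are both accepted and stored as given (case-folded).
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ParseError(f"{path}: duplicate FASTA record name {record.id!r}")
        seq = str(record.seq).upper()
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTUN"))
            raise ParseError(f"{path}: record {record.id!r} has invalid characters {bad}")
        out[record.id] = seq
    return out


def read_site_table(path, one_based: bool = False, normalize_chrom: bool = False) -> list[EditingSite]:
    """Read a headered TSV of editing sites.

    Mandatory columns: chrom, pos, strand, region, tissue_derived,
    on_refseq, source. ``one_based=True`` converts a 1-based pos column to
    the internal 0-based convention on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "source": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: site table missing columns {missing}")
    sites = []
    for row in df.itertuples(index=False):
        pos = int(row.pos) - 1 if one_based else int(row.pos)
        sites.append(
            EditingSite(
                chrom=_normalize_chrom(str(row.chrom), normalize_chrom),
                pos=pos,
                strand=str(row.strand),
                region=str(row.region),
                tissue_derived=_as_bool(row.tissue_derived),
                on_refseq=_as_bool(row.on_refseq),
                source="" if pd.isna(row.source) else str(row.source),
            )
        )
    return sites


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


def sites_to_frame(sites) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "strand": s.strand,
                "region": s.region,
                "tissue_derived": s.tissue_derived,
                "on_refseq": s.on_refseq,
                "source": s.source,
            }
            for s in sites
        ],
        columns=SITE_COLUMNS,
    )


def write_site_table(sites, path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)
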