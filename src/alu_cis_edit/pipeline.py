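"""End-to-end orchestration: inputs -> filter -> proximity -> conservation -> report.

The pipeline runs either on real input files or on the synthetic
generator, applies the inclusion filters and cluster removal, computes
signed nearest-edited-Alu distances for the retained sites and for a
random-adenosine null sample, runs the orientation and distance-
enrichment tests, optionally runs the conservation contrast, and writes
TSV tables plus one consolidated JSON report. Identical config and seed
give an identical report (timings aside).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict

import pandas as pd

from . import __version__
from . import io as aio
from .conservation import GroupingConfig, analyze_conservation
from .filtering import FilterConfig, apply_inclusion_filters, detect_clusters, \
    partition_and_flag, remove_clustered
from .proximity import EditedAluIndex, HistogramSpec, NullConfig, \
    compare_distance_distributions, compute_distance_records, distance_histogram, \
    orientation_test, sample_random_adenosines
from .simulate import SyntheticConfig, simulate_conservation, simulate_genome, \
    simulate_pool, simulate_sites, write_outputs

log = logging.getLogger("alu_cis_edit")


class ConfigError(ValueError):
    """Bad or missing pipeline configuration."""


DEFAULTS = {
    "seed": 0,
    "n_null": 20_000,
    "window": 20_000,
    "bin_width": 100,
    "orient_window": 2_000,
    "orient_bin": 10,
    "proximal_threshold": 1_000,
    "min_coverage": 16,
    "flank": 15,
    "welch": True,
    "exon_trim": True,  # trim conservation windows to exons (needs gene models)
}


def _stage(report, name, t0):
    report["timings_s"][name] = round(time.perf_counter() - t0, 4)


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run every stage and return the consolidated report (also written to disk).

    ``config`` holds either a ``synthetic`` block (SyntheticConfig fields)
    or an ``inputs`` block with paths (sites, alus, genes, pool, optional
    conservation), plus optional analysis parameters (filter thresholds,
    null size, histogram geometry, seed).
    """
    os.makedirs(outdir, exist_ok=True)
    params = {**DEFAULTS, **{k: v for k, v in config.items() if k in DEFAULTS}}
    fconf = FilterConfig(**config.get("filter", {}))
    report = {
        "version": __version__,
        "seed": params["seed"],
        "config": {k: v for k, v in config.items() if k != "synthetic"},
        "timings_s": {},
        "stages": {},
    }

    # ---- stage: inputs -------------------------------------------------
    t0 = time.perf_counter()
    track = None
    if "synthetic" in config:
        syn = SyntheticConfig(**{"seed": params["seed"], **config["synthetic"]})
        report["config"]["synthetic"] = asdict(syn)
        log.info("[inputs] simulating genome and sites (seed=%d)", syn.seed)
        genome = simulate_genome(syn)
        sites, truth = simulate_sites(syn, genome)
        pool = simulate_pool(syn, genome)
        genes, alus = genome.genes, genome.alus
        report["stages"]["inputs"] = {"mode": "synthetic", "truth": truth}
        syn_genome = genome
    elif "inputs" in config:
        paths = config["inputs"]
        for key in ("sites", "alus"):
            if key not in paths:
                raise ConfigError(f"inputs stage: missing mandatory input '{key}'")
            if not os.path.exists(paths[key]):
                raise ConfigError(f"inputs stage: file not found: {paths[key]}")
        sites = aio.read_site_table(paths["sites"], one_based=paths.get("one_based", False))
        alus = aio.read_alus(paths["alus"])
        genes = aio.read_gene_models(paths["genes"]) if paths.get("genes") else []
        pool = [
            type(sites[0])(chrom=iv.chrom, pos=iv.start, strand=iv.strand,
                           region=iv.name if iv.name else "unknown", source="pool")
            for iv in aio.read_bed_intervals(paths["pool"])
        ] if paths.get("pool") else []
        if paths.get("conservation"):
            track = aio.read_score_track(paths["conservation"])
        report["stages"]["inputs"] = {"mode": "files", "paths": dict(paths)}
        syn_genome = None
    else:
        raise ConfigError("config needs a 'synthetic' or an 'inputs' block")
    report["stages"]["inputs"]["n_sites"] = len(sites)
    report["stages"]["inputs"]["n_alus"] = len(alus)
    report["stages"]["inputs"]["n_genes"] = len(genes)
    report["stages"]["inputs"]["n_pool"] = len(pool)
    _stage(report, "inputs", t0)

    # ---- stage: filter -------------------------------------------------
    t0 = time.perf_counter()
    log.info("[filter] inclusion filters + Alu partition + cluster removal")
    included = apply_inclusion_filters(sites, genes=genes or None, config=fconf)
    non_alu, alu_sites, flagged = partition_and_flag(included, alus)
    clusters = detect_clusters(non_alu, fconf)
    retained, n_removed = remove_clustered(non_alu, clusters, fconf.cluster_per_strand)
    n_edited = sum(1 for a in flagged if a.edited)
    report["stages"]["filter"] = {
        "n_input": len(sites),
        "n_included": len(included),
        "n_non_alu": len(non_alu),
        "n_alu": len(alu_sites),
        "n_edited_alus": n_edited,
        "n_clusters": len(clusters),
        "n_removed": n_removed,
        "n_retained": len(retained),
    }
    aio.write_site_table(retained, os.path.join(outdir, "sites_retained.tsv"))
    removed_keys = {s.key for s in non_alu} - {s.key for s in retained}
    aio.write_site_table([s for s in non_alu if s.key in removed_keys],
                         os.path.join(outdir, "sites_removed.tsv"))
    _stage(report, "filter", t0)

    # ---- stage: proximity ----------------------------------------------
    t0 = time.perf_counter()
    if n_edited == 0:
        raise ConfigError("proximity stage: no edited Alus after partitioning")
    log.info("[proximity] distances for %d sites and the random-adenosine null",
             len(retained))
    index = EditedAluIndex(flagged)
    records = compute_distance_records(retained, index, genes=genes or None)
    defined = [r for r in records if r is not None]
    null_stats = None
    if pool:
        n_null = min(params["n_null"], len(pool))
        null_sample = sample_random_adenosines(
            pool, NullConfig(n_samples=n_null, seed=params["seed"]))
        null_records = compute_distance_records(null_sample, index, genes=genes or None)
        null_defined = [r for r in null_records if r is not None]
        null_stats = compare_distance_distributions(
            [r.genomic_gap for r in defined],
            [r.genomic_gap for r in null_defined],
            welch=params["welch"],
        )
    orient = orientation_test(defined, max_distance=params["orient_window"])
    hist_u = distance_histogram(defined, HistogramSpec(
        window=params["window"], bin_width=params["bin_width"], signed=False))
    hist_s = distance_histogram(defined, HistogramSpec(
        window=params["orient_window"], bin_width=params["orient_bin"], signed=True))
    pd.DataFrame([
        {"chrom": r.site.chrom, "pos": r.site.pos, "alu": r.alu_name,
         "gap": r.genomic_gap, "signed_distance": r.signed_distance}
        for r in defined
    ]).to_csv(os.path.join(outdir, "distances.tsv"), sep="\t", index=False)
    hist_u.table.to_csv(os.path.join(outdir, "hist_unsigned.tsv"), sep="\t", index=False)
    hist_s.table.to_csv(os.path.join(outdir, "hist_signed.tsv"), sep="\t", index=False)
    report["stages"]["proximity"] = {
        "n_records": len(defined),
        "n_no_alu_chrom": len(records) - len(defined),
        "orientation": orient,
        "distance_test": null_stats,
        "hist_unsigned_excluded": hist_u.n_excluded,
        "hist_signed_excluded": hist_s.n_excluded,
    }
    _stage(report, "proximity", t0)

    # ---- stage: conservation -------------------------------------------
    t0 = time.perf_counter()
    if track is None and syn_genome is not None and "synthetic" in config \
            and config.get("simulate_conservation", True):
        track = simulate_conservation(syn, retained, records)
    if track is None:
        log.info("[conservation] no score track supplied; stage skipped")
        report["stages"]["conservation"] = {"status": "skipped"}
    else:
        grouping = GroupingConfig(
            proximal_threshold=params["proximal_threshold"],
            min_coverage=params["min_coverage"],
            flank=params["flank"],
        )
        cons = analyze_conservation(
            retained, records, track,
            genes=(genes or None) if params["exon_trim"] else None,
            grouping=grouping)
        cons["status"] = "ok"
        report["stages"]["conservation"] = cons
    _stage(report, "conservation", t0)

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


def validate_inputs(paths: dict) -> list[dict]:
    """Schema and sanity findings for a set of input files; never mutates them.

    Returns a list of findings {level, file, message}; an empty list means
    every supplied file parsed and the chromosome namespaces overlap.
    """
    findings: list[dict] = []
    chroms: dict[str, set] = {}

    def check(key, loader):
        path = paths.get(key)
        if not path:
            return None
        if not os.path.exists(path):
            findings.append({"level": "error", "file": path, "message": "file not found"})
            return None
        try:
            return loader(path)
        except Exception as exc:  # findings are the output, not exceptions
            findings.append({"level": "error", "file": path, "message": str(exc)})
            return None

    sites = check("sites", aio.read_site_table)
    if sites is not None:
        chroms["sites"] = {s.chrom for s in sites}
    alus = check("alus", aio.read_bed_intervals)
    if alus is not None:
        chroms["alus"] = {a.chrom for a in alus}
    genes = check("genes", aio.read_gene_models)
    if genes is not None:
        chroms["genes"] = {g.chrom for g in genes}
    pool = check("pool", aio.read_bed_intervals)
    if pool is not None:
        chroms["pool"] = {p.chrom for p in pool}
    track = check("conservation", aio.read_score_track)
    if track is not None:
        chroms["conservation"] = set(track.chroms())

    names = list(chroms)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if chroms[a] and chroms[b] and not (chroms[a] & chroms[b]):
                findings.append({
                    "level": "warning",
                    "file": f"{a}+{b}",
                    "message": f"no shared chromosomes between {a} and {b}",
                })
    return findings
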