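#!/usr/bin/env python
"""Apply the inclusion filters, partition Alu vs non-Alu, remove clusters.

Reads the dataset written by 01_simulate.py, keeps tissue-derived sites on
transcripts, splits sites into Alu/non-Alu (flagging Alus containing a
site as edited), removes hyper-editing clusters (>= 3 sites, consecutive
gaps <= 40 nt, span >= 70 nt), and writes the retained/removed tables and
a summary under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

from alu_cis_edit import io as aio
from alu_cis_edit.filtering import (
    FilterConfig, apply_inclusion_filters, detect_clusters, partition_and_flag,
    remove_clustered,
)

BASE = os.path.join(os.path.dirname(__file__), os.pardir, "results")
DATA = os.path.join(BASE, "synthetic")

sites = aio.read_site_table(os.path.join(DATA, "sites.tsv"))
alus = aio.read_alus(os.path.join(DATA, "alus.bed"))
genes = aio.read_gene_models(os.path.join(DATA, "genes.bed"))

conf = FilterConfig()
included = apply_inclusion_filters(sites, genes=genes, config=conf)
non_alu, alu_sites, flagged = partition_and_flag(included, alus)
clusters = detect_clusters(non_alu, conf)
retained, n_removed = remove_clustered(non_alu, clusters)

aio.write_site_table(retained, os.path.join(BASE, "sites_retained.tsv"))
summary = {
    "n_input": len(sites), "n_included": len(included),
    "n_non_alu": len(non_alu), "n_alu": len(alu_sites),
    "n_edited_alus": sum(a.edited for a in flagged),
    "n_clusters": len(clusters), "n_removed": n_removed,
    "n_retained": len(retained),
}
with open(os.path.join(BASE, "filter_summary.json"), "w") as fh:
    json.dump(summary, fh, indent=1)

print(f"{summary['n_included']} sites pass inclusion; "
      f"{summary['n_alu']} inside Alus mark {summary['n_edited_alus']} Alus edited")
print(f"cluster filter: {summary['n_clusters']} clusters, "
      f"{summary['n_removed']} sites removed, {summary['n_retained']} retained")
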