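# alu-cis-edit

Analysis pipeline for studying how **site-selective A-to-I RNA editing**
relates to nearby **edited Alu elements**. Inverted Alu repeats can fold
into long RNA duplexes that recruit ADAR enzymes; the question this
pipeline addresses is whether individually edited adenosines outside Alu
repeats sit closer to edited Alus than chance predicts, whether the Alu
tends to lie downstream of the site in transcript orientation, and
whether sequence flanking Alu-proximal sites is less conserved than
sequence flanking distal sites (consistent with the duplex, not the local
sequence, driving editing).

The pipeline:

1. **Compile & filter** — ingest a site table, keep tissue-derived sites
   on annotated transcripts, collapse duplicates, partition sites into
   Alu/non-Alu (an Alu containing a site is flagged *edited*), and remove
   hyper-editing clusters: ≥ 3 sites with consecutive gaps ≤ 40 nt
   spanning ≥ 70 nt first-to-last.
2. **Proximity** — for each retained site, the signed transcript-oriented
   distance *d* to the nearest edited Alu edge (*d* > 0: Alu downstream).
   The null is the same computation on adenosine positions sampled
   uniformly from a SNP-derived pool outside Alus. Tests: Welch two-sample
   *t* on |*d*| (observed vs null) and an exact binomial test of the
   downstream fraction among sites with |*d*| ≤ 2 kb.
3. **Conservation** — per-site mean conservation score over the site
   ± 15 nt, trimmed to the host exon; sites ≤ 1 kb from an edited Alu
   (proximal) vs > 1 kb (distal) compared by *t* and Mann–Whitney tests.
4. **Effects** — editing level from chromatogram peaks,
   % = 100·G/(A+G), classified non/low/medium/high/full; and an
   editing-aware miRNA seed scanner (positions 2–8, G:U wobble allowed)
   that reports whether an A→G edit creates, destroys or retains a seed
   match.
5. **Synthetic data** — a generator that plants all of the above
   structure (proximity mixture, orientation bias, clusters, conservation
   effect) with known ground truth, so every stage is testable end to end
   without downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each writes its tables under `results/`):

```sh
python analysis/01_simulate.py
python analysis/02_filter_sites.py
python analysis/03_proximity.py
python analysis/04_conservation.py
python analysis/05_editing_effects.py
```

With the default configuration (5,000 non-Alu sites, proximity mixture
π = 0.6, decay scale λ = 400 nt, downstream bias 0.56) this prints:

```
6968 sites pass inclusion; 1948 inside Alus mark 974 Alus edited
cluster filter: 7 clusters, 27 sites removed, 4993 retained
observed mean distance 11056 nt vs null 25783 nt (Welch t-test p = 0)
within 2 kb the edited Alu is downstream for 55.3% of sites (binomial p = 5.33e-09)
proximal (<=1 kb) n=2690 mean=0.423; distal (>1 kb) n=2303 mean=0.595
t-test p = 0; Mann-Whitney p = 0
ultra-conserved mode: 102 distal windows in the top score bin
```

Reading this: the in-Alu sites mark which Alus are edited; the cluster
filter strips the planted hyper-editing clusters plus a handful of chance
chains; retained sites are on average far closer to edited Alus than
random adenosines (a *p*-value that underflows to 0); the downstream
fraction recovers the planted 0.56 bias; and the conservation contrast
recovers the planted 0.2 difference in window means, with the
ultra-conserved component visible in the top histogram bin.

The same steps run from the command line on real files
(`alu-cis-edit simulate|filter|proximity|conservation|quantify|mirna-scan|run|validate`);
inputs are plain BED6/BED12, bedGraph/WIG, FASTA and headered TSV site
tables (0-based half-open internally; a `--one-based` flag converts
published 1-based tables on read).

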