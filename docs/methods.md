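# Methods

## Model and rationale

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA.
Long duplexes formed by inverted Alu pairs are edited promiscuously
(many clustered sites); site-selective editing of single adenosines in
short hairpins is rarer and functionally consequential. If an inverted
Alu pair can act as a *cis* recruitment element for editing of nearby
non-Alu adenosines, three statistical signatures follow, and the
pipeline measures each:

1. non-Alu editing sites are closer to edited Alus than matched random
   adenosines;
2. the nearest edited Alu is preferentially downstream of the site in
   transcript orientation;
3. sequence flanking Alu-proximal sites is under weaker conservation
   than sequence flanking distal (Alu-independent) sites, whose hairpin
   must be maintained by selection.

## Conventions

* All coordinates are 0-based half-open (BED-native). 1-based output is
  presentation-layer only (`start + 1` exactly); 1-based input site
  tables are converted on read via a dialect flag.
* **Distance**: the gap between a site and the nearest edge of an Alu is
  counted so that an immediately adjacent site has gap 1
  (`alu.start − pos` for an Alu to the right; `pos − (alu.end − 1)` to
  the left). This keeps |d| ≥ 1 as an invariant for non-contained sites.
  A site inside an edited Alu is a contract violation (partitioning must
  precede distance computation).
* **Orientation**: positive = Alu downstream of the site in transcript
  coordinates, resolved through the host gene's strand (fallback: the
  site's own strand; unresolvable strands keep the unsigned distance but
  are excluded from orientation tests). Equidistant candidates break
  ties deterministically to downstream; the (rare) bias is auditable.
  The null uses the identical routine, so convention biases cancel.
* **Clusters**: maximal chains with consecutive gaps ≤ 40 nt, reported
  when ≥ 3 members span ≥ 70 nt inclusive (`last − first + 1`). Chaining
  is per (chromosome, strand) when strand is known — editing is a
  transcript-level event. "Up to 40 nt from each other" is read as
  consecutive-gap chaining, not all-pairs distance: an all-pairs reading
  would cap a cluster at 40 nt total and contradict the 70 nt span
  requirement. Both the inclusive/exclusive span convention and all
  thresholds are configurable.
* **Editing level**: % = 100·G/(A+G) from chromatogram peak heights;
  classes are lower-inclusive half-open — non [0,10), low [10,25),
  medium [25,50), high [50,75), full [75,100] — so the partition is
  total and non-overlapping at the shared endpoints, which prose ranges
  ("10% to 25%", "25% to 50%") leave ambiguous.
* **Seed scan**: miRNA positions 2–8 (1-based from the 5′ end) are
  paired antiparallel against every target heptamer; A:U and G:C are
  Watson–Crick, G:U is a wobble; a window is reported when
  WC + wobble ≥ 7 and wobble ≤ 1 by default. "One wobble site" is read
  as *at most* one (a flag requires exactly one). U and T are
  interchangeable throughout. Only the match-count seed model is
  implemented; thermodynamic (ΔΔG) scoring is out of scope. Edited bases
  are substituted as G, since inosine is read as guanosine.

## Statistical choices

* The distance comparison defaults to Welch's unequal-variance t-test:
  observed distances concentrate near zero while null distances are
  spread over gene bodies, so group variances differ grossly. Pooled
  Student is available behind a flag.
* The orientation test is an exact two-sided binomial test against 0.5,
  restricted to |d| ≤ 2 kb where the recruitment model operates.
* The conservation contrast reports a Welch t-test and a Mann–Whitney
  U-test side by side on every comparison rather than pairing one test
  with one score type.
* Degenerate inputs: two zero-variance samples with equal means give
  p = 1 (not an error); a conservation window needs ≥ 16 of its ≤ 31
  positions covered (`min_coverage`) for a defined mean — a majority
  rule that stops means being dominated by one or two scored bases.
* The proximal/distal threshold is inclusive at exactly 1,000 nt.

## Synthetic data generator

The generator emulates the data-generating process the analysis assumes,
with every parameter explicit in `SyntheticConfig`:

* **Genome**: per chromosome, genes in regular slots (default 2 chroms ×
  25 Mb, 100 genes each, slot 250 kb with a 10% margin), five 600 nt
  exons per gene evenly spaced, and five Alu pairs per gene (300 nt
  members, 60 nt intra-pair gap, opposite strands for inverted pairs)
  placed uniformly in introns by rejection sampling. Each Alu is edited
  with probability 0.5 and receives two in-Alu editing sites, so the
  partitioning stage derives the edited flag from the site table exactly
  as it would on real data. Defaults give ~1,000 edited Alus against
  ~3,000 mechanism-placed sites — like the real transcriptome, sites per
  edited Alu stay of order one, so chance hyper-editing-like chains are
  rare.
* **Sites**: each of `n_sites` non-Alu sites is mechanism-placed with
  probability π (default 0.6): pick a random edited Alu, draw
  |d| ~ Exponential(λ = 400 nt) rounded up to ≥ 1, and place the site so
  the Alu is downstream with probability `p_down` = 0.56 in transcript
  orientation. The offset is taken from the *pair envelope* rather than
  the bare Alu: offsets from one member would be rejected whenever they
  land inside the partner, which silently erases the orientation bias.
  Draws landing inside any Alu or outside the host gene are redrawn
  (capped at 1,000, then an error — no silent distribution distortion).
  The remaining sites are uniform over gene bodies outside Alus.
  Injected clusters (configurable count/size/spacing) and the
  ground-truth label of every site are recorded. The exponential decay
  is a one-parameter stand-in for the observed monotone decay of
  enrichment within 1–2 kb; no specific functional form is claimed.
* **Null pool**: uniform gene-body positions outside Alus with region
  labels, mimicking a SNP-derived adenosine pool.
* **Conservation**: windows (site ± 15 nt) around proximal sites draw
  iid scores from a [0,1]-truncated Normal(0.4, 0.25); distal windows
  from Normal(0.6, 0.25); a configurable fraction of distal windows is
  pinned at 1.0 (the ultra-conserved component). First writer wins where
  windows overlap. Positions outside windows are uncovered.
* **Peak tables**: A/G heights encode a true editing percentage plus
  Gaussian noise (default SD 2 percentage points, clipped to [0,100]);
  C/T are small nuisance heights.
* All randomness flows from one master seed through fixed per-component
  substreams; equal configs give byte-identical outputs.

What the generator does **not** emulate: real sequence content (no Alu
consensus or RNA structure), transcript isoform complexity, coverage-
dependent site ascertainment, correlated conservation along the genome,
or region-class composition biases of SNP pools. Passing tests therefore
demonstrate that the statistics recover planted structure under the
stated model, not that the model describes any particular dataset.

## Problem sizes in tests and the acceptance script

The acceptance run and the parameter-recovery test use the full study
conditions (5,000 sites, π = 0.6, λ = 400, p_down = 0.56, 20,000-position
null) on the default 50 Mb two-chromosome genome — about three seconds
end to end. Calibration and power checks use 100 seeded replicates of a
4 Mb single-chromosome genome with 400 sites each, enough for the
envelope/error-rate assertions while keeping the whole suite under a
minute. Oracle-equivalence checks run 1,000 randomized instances each
against brute-force reimplementations (exhaustive chain enumeration; an
O(n) linear scan over all Alus).

A note on the recovered downstream fraction: background sites that fall
within 2 kb of an edited Alu by chance enter the orientation test with
an unbiased 0.5 split, so the recovered fraction sits slightly below the
planted 0.56 (≈ 0.555 at the default geometry). This dilution is part of
the model — the real analysis has the same property — and is well inside
the ±0.02 recovery tolerance.

## Known limitations

* Cluster removal can delete mechanism-placed sites that form chance
  chains near a heavily targeted Alu; with the default (realistically
  sparse) geometry this affects a few dozen of 5,000 sites and is
  orientation-neutral.
* Host-gene resolution for orientation picks the lowest-indexed gene
  when genes overlap; deterministic, but arbitrary for overlapping loci.
* The bedGraph/WIG reader materialises per-base scores; it is meant for
  track slices covering the analysed windows, not whole-genome tracks
  (bigWig conversion is the user's job).
* Region annotations (missense/UTR/…) are consumed as an input column,
  never re-derived from gene models.
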