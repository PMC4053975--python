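"""Generator contracts: geometry, placement mixture, determinism, round-trips."""

import json

import numpy as np
import pytest
from scipy import stats

from alu_cis_edit import io as aio
from alu_cis_edit.proximity import EditedAluIndex, compute_distance_records
from alu_cis_edit.simulate import (
    GeometryError, SyntheticConfig, simulate_conservation, simulate_genome,
    simulate_peak_table, simulate_pool, simulate_sites, write_outputs,
)
from alu_cis_edit.effects import PeakHeights, editing_percent
from alu_cis_edit.filtering import build_interval_index


def tiny(**kw):
    base = dict(n_chroms=1, chrom_length=600_000, n_genes=3, n_alu_pairs_per_gene=2,
                n_sites=60, pool_size=120, seed=7)
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenome:
    def test_alu_count_bookkeeping(self):
        genome = simulate_genome(tiny())
        assert len(genome.alus) == 3 * 2 * 2  # genes x pairs x members
        assert len(genome.genes) == 3

    def test_inverted_pairs_have_opposite_strands(self):
        genome = simulate_genome(tiny(inverted_pair_fraction=1.0))
        for a, b in zip(genome.alus[::2], genome.alus[1::2]):
            assert {a.interval.strand, b.interval.strand} == {"+", "-"}

    def test_edited_fraction_within_binomial_envelope(self):
        conf = SyntheticConfig(n_chroms=1, chrom_length=4_000_000, n_genes=20,
                               n_alu_pairs_per_gene=10, edited_alu_fraction=0.5, seed=3)
        genome = simulate_genome(conf)
        n = len(genome.alus)
        assert n == 400
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= sum(a.edited for a in genome.alus) <= hi

    def test_alus_inside_host_gene_and_disjoint(self):
        genome = simulate_genome(tiny())
        for a, host in zip(genome.alus, genome.alu_host):
            span = genome.genes[host].span
            assert span[0] <= a.interval.start and a.interval.end <= span[1]
        ivs = sorted((a.interval.start, a.interval.end) for a in genome.alus)
        assert all(x[1] <= y[0] or x[0] >= y[1] for x, y in zip(ivs, ivs[1:]))

    def test_infeasible_geometry_errors_before_output(self):
        with pytest.raises(GeometryError):
            simulate_genome(tiny(chrom_length=5_000))

    def test_determinism(self):
        a = simulate_genome(tiny())
        b = simulate_genome(tiny())
        assert [x.interval for x in a.alus] == [x.interval for x in b.alus]
        assert [x.edited for x in a.alus] == [x.edited for x in b.alus]


class TestSites:
    def test_no_non_alu_site_ever_overlaps_an_alu(self):
        conf = tiny(n_sites=200)
        genome = simulate_genome(conf)
        sites, _ = simulate_sites(conf, genome)
        trees = build_interval_index([a.interval for a in genome.alus])
        for s in sites:
            hit = bool(trees.get(s.chrom) and trees[s.chrom][s.pos])
            assert hit == (s.source == "alu")

    def test_pi_zero_places_no_mechanism_sites(self):
        conf = tiny(pi=0.0)
        sites, truth = simulate_sites(conf, simulate_genome(conf))
        assert truth["n_mechanism"] == 0

    def test_pi_one_short_decay_concentrates_near_alus(self):
        conf = tiny(pi=1.0, lam=300.0, n_sites=1000, chrom_length=2_000_000,
                    n_genes=10, n_alu_pairs_per_gene=3)
        genome = simulate_genome(conf)
        sites, _ = simulate_sites(conf, genome)
        mech = [s for s in sites if s.source == "mechanism"]
        recs = compute_distance_records(mech, EditedAluIndex(genome.alus),
                                        genes=genome.genes)
        frac = np.mean([r.genomic_gap <= 2000 for r in recs if r is not None])
        # exponential CDF: P(|d| <= 2000) = 1 - exp(-2000/300) ~ 0.9987
        assert frac >= 0.99

    def test_mechanism_requires_an_edited_alu(self):
        conf = tiny(pi=0.5, edited_alu_fraction=0.0)
        with pytest.raises(ValueError, match="edited Alu"):
            simulate_sites(conf, simulate_genome(conf))

    def test_same_seed_byte_identical_site_table(self, tmp_path):
        conf = tiny()
        for name in ("a.tsv", "b.tsv"):
            genome = simulate_genome(conf)
            sites, _ = simulate_sites(conf, genome)
            aio.write_site_table(sites, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_injected_clusters_have_requested_geometry(self):
        conf = tiny(n_injected_clusters=2, cluster_sites=4, cluster_gap=30)
        sites, truth = simulate_sites(conf, simulate_genome(conf))
        assert truth["n_cluster"] == 8
        for chrom, members in truth["cluster_positions"]:
            gaps = np.diff(members)
            assert list(gaps) == [30, 30, 30]


class TestConservationTrack:
    def _setup(self, **kw):
        conf = tiny(n_sites=200, chrom_length=2_000_000, n_genes=10,
                    n_alu_pairs_per_gene=3, **kw)
        genome = simulate_genome(conf)
        sites, _ = simulate_sites(conf, genome)
        non_alu = [s for s in sites if s.source != "alu"]
        recs = compute_distance_records(non_alu, EditedAluIndex(genome.alus),
                                        genes=genome.genes)
        return conf, non_alu, recs

    def test_scores_within_unit_interval(self):
        conf, sites, recs = self._setup()
        track = simulate_conservation(conf, sites, recs)
        for chrom in track.chroms():
            scores, mask = track.get_many(chrom, track._pos[chrom])
            assert mask.all() and (scores >= 0).all() and (scores <= 1).all()

    def test_ultra_conserved_windows_pin_to_one(self):
        conf, sites, recs = self._setup(ultra_conserved_fraction=1.0,
                                        cons_mu_distal=0.5)
        track = simulate_conservation(conf, sites, recs)
        distal = [s for s, r in zip(sites, recs)
                  if r is not None and r.genomic_gap > conf.cons_proximal_threshold]
        assert distal
        for s in distal[:20]:
            assert track.get(s.chrom, s.pos) == 1.0

    def test_proximal_and_distal_means_separate(self):
        conf, sites, recs = self._setup(cons_mu_proximal=0.2, cons_mu_distal=0.8,
                                        cons_sd=0.1)
        track = simulate_conservation(conf, sites, recs)
        prox = [track.get(s.chrom, s.pos) for s, r in zip(sites, recs)
                if r is not None and r.genomic_gap <= 1000]
        dist = [track.get(s.chrom, s.pos) for s, r in zip(sites, recs)
                if r is not None and r.genomic_gap > 1000]
        assert np.mean(prox) < 0.5 < np.mean(dist)


class TestPeakTable:
    def test_zero_noise_recovers_truth_exactly(self):
        df = simulate_peak_table([0, 12.5, 37, 100], noise_sd=0.0, seed=1)
        got = [editing_percent(PeakHeights(r.A, r.C, r.G, r.T))
               for r in df.itertuples(index=False)]
        assert got == pytest.approx([0, 12.5, 37, 100])

    def test_half_editing_balances_peaks(self):
        df = simulate_peak_table([50], noise_sd=0.0, seed=1)
        assert df.A.iloc[0] == pytest.approx(df.G.iloc[0])

    def test_seed_determinism(self):
        a = simulate_peak_table([10, 90], noise_sd=3.0, seed=5)
        b = simulate_peak_table([10, 90], noise_sd=3.0, seed=5)
        assert a.equals(b)


def test_written_outputs_are_valid_pipeline_inputs(tmp_path):
    conf = tiny(n_sites=80)
    genome = simulate_genome(conf)
    sites, truth = simulate_sites(conf, genome)
    pool = simulate_pool(conf, genome)
    non_alu = [s for s in sites if s.source != "alu"]
    recs = compute_distance_records(non_alu, EditedAluIndex(genome.alus),
                                    genes=genome.genes)
    track = simulate_conservation(conf, non_alu, recs)
    peaks = simulate_peak_table([37.0], seed=conf.seed)
    paths = write_outputs(tmp_path, conf, genome, sites, truth, pool, track, peaks)

    assert aio.read_site_table(paths["sites"]) == sites
    assert len(aio.read_bed_intervals(paths["alus"])) == len(genome.alus)
    assert len(aio.read_bed_intervals(paths["edited_alus"])) == \
        sum(a.edited for a in genome.alus)
    genes_back = aio.read_gene_models(paths["genes"])
    assert len(genes_back) == len(genome.genes)
    back = aio.read_score_track(paths["conservation"])
    assert back.n_covered() == track.n_covered()
    with open(paths["truth"]) as fh:
        assert json.load(fh)["truth"]["n_mechanism"] == truth["n_mechanism"]
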