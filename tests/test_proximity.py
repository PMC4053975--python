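"""Nearest-edited-Alu distances, the random null, and the proximity statistics."""

import math

import numpy as np
import pytest

from alu_cis_edit.proximity import (
    EditedAluIndex, HistogramSpec, NullConfig, compare_distance_distributions,
    compute_distance_records, distance_histogram, nearest_edited_alu,
    orientation_test, sample_random_adenosines,
)

from conftest import make_alu, make_site


def linear_scan_oracle(pos, alus, strand):
    """Full O(n) scan: gap to every edited Alu edge, then min with
    downstream tie-break. Returns (gap, signed) or None."""
    best = None
    for a in alus:
        if not a.edited:
            continue
        iv = a.interval
        if iv.start <= pos < iv.end:
            raise AssertionError("oracle applied to an in-Alu position")
        if iv.start > pos:  # Alu right of site
            gap, down = iv.start - pos, strand == "+"
        else:  # Alu left of site
            gap, down = pos - (iv.end - 1), strand == "-"
        rank = (gap, 0 if down else 1)  # tie -> downstream
        if best is None or rank < best[0]:
            best = (rank, gap, gap if down else -gap)
    return None if best is None else (best[1], best[2])


class TestNearest:
    def test_worked_example_plus_strand(self):
        alus = [make_alu(start=1500, end=1800, name="right"),
                make_alu(start=200, end=260, name="left")]
        rec = nearest_edited_alu(make_site(pos=1000), EditedAluIndex(alus), "+")
        assert rec.genomic_gap == 500 and rec.signed_distance == 500
        assert rec.alu_name == "right"

    def test_sign_flips_on_minus_strand_gene(self):
        alus = [make_alu(start=1500, end=1800), make_alu(start=200, end=260)]
        rec = nearest_edited_alu(make_site(pos=1000), EditedAluIndex(alus), "-")
        assert rec.signed_distance == -500

    def test_no_edited_alu_on_chromosome_gives_none(self):
        idx = EditedAluIndex([make_alu(chrom="chr2")])
        assert nearest_edited_alu(make_site(chrom="chr1", pos=10), idx, "+") is None

    def test_site_inside_edited_alu_is_contract_violation(self):
        idx = EditedAluIndex([make_alu(start=100, end=200)])
        with pytest.raises(ValueError, match="inside"):
            nearest_edited_alu(make_site(pos=150), idx, "+")

    def test_adjacent_site_has_gap_one(self):
        idx = EditedAluIndex([make_alu(start=100, end=200)])
        assert nearest_edited_alu(make_site(pos=99), idx, "+").genomic_gap == 1
        assert nearest_edited_alu(make_site(pos=200), idx, "+").genomic_gap == 1

    def test_equidistant_tie_breaks_downstream(self):
        # gaps: left alu ends at 101 -> 150-100 = 50; right alu starts at 200 -> 50
        alus = [make_alu(start=0, end=101, name="up"),
                make_alu(start=200, end=300, name="down")]
        rec = nearest_edited_alu(make_site(pos=150), EditedAluIndex(alus), "+")
        assert rec.genomic_gap == 50 and rec.signed_distance == 50
        assert rec.alu_name == "down"
        rec_minus = nearest_edited_alu(make_site(pos=150), EditedAluIndex(alus), "-")
        assert rec_minus.alu_name == "up" and rec_minus.signed_distance == 50

    def test_matches_linear_scan_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n_alu = int(rng.integers(1, 50))
            alus = []
            for k in range(n_alu):
                start = int(rng.integers(0, 50_000))
                alus.append(make_alu(start=start, end=start + int(rng.integers(50, 400)),
                                     name=f"a{k}", edited=bool(rng.random() < 0.7)))
            idx = EditedAluIndex(alus)
            for _ in range(20):
                pos = int(rng.integers(0, 55_000))
                strand = "+" if rng.random() < 0.5 else "-"
                try:
                    expected = linear_scan_oracle(pos, alus, strand)
                except AssertionError:
                    continue  # in-Alu positions are a different contract
                rec = nearest_edited_alu(make_site(pos=pos, strand=strand), idx, strand)
                if expected is None:
                    assert rec is None
                else:
                    assert (rec.genomic_gap, rec.signed_distance) == expected

    def test_adding_a_farther_alu_never_changes_the_result(self):
        alus = [make_alu(start=1500, end=1800, name="near")]
        rec = nearest_edited_alu(make_site(pos=1000), EditedAluIndex(alus), "+")
        farther = alus + [make_alu(start=5000, end=5300, name="far"),
                          make_alu(start=100, end=150, name="farleft")]
        rec2 = nearest_edited_alu(make_site(pos=1000), EditedAluIndex(farther), "+")
        assert (rec.genomic_gap, rec.signed_distance, rec.alu_name) == \
               (rec2.genomic_gap, rec2.signed_distance, rec2.alu_name)

    def test_unresolvable_strand_keeps_unsigned_gap(self):
        idx = EditedAluIndex([make_alu(start=1500, end=1800)])
        rec = nearest_edited_alu(make_site(pos=1000, strand="."), idx, None)
        assert rec.genomic_gap == 500 and rec.signed_distance is None


class TestNullSampling:
    def test_exhaustive_sample_returns_whole_pool(self):
        pool = [make_site(pos=i) for i in range(5)]
        out = sample_random_adenosines(pool, NullConfig(n_samples=5, seed=1))
        assert sorted(s.pos for s in out) == [0, 1, 2, 3, 4]

    def test_same_seed_same_sample(self):
        pool = [make_site(pos=i) for i in range(100)]
        a = sample_random_adenosines(pool, NullConfig(n_samples=10, seed=9))
        b = sample_random_adenosines(pool, NullConfig(n_samples=10, seed=9))
        assert [s.pos for s in a] == [s.pos for s in b]

    def test_oversampling_is_an_error(self):
        with pytest.raises(ValueError, match="pool"):
            sample_random_adenosines([make_site()], NullConfig(n_samples=2, seed=0))

    def test_zero_weight_class_never_drawn(self):
        pool = [make_site(pos=i, region="intron" if i % 2 else "utr3")
                for i in range(2000)]
        conf = NullConfig(n_samples=500, seed=3,
                          class_weights={"intron": 0.0, "utr3": 1.0})
        drawn = sample_random_adenosines(pool, conf)
        assert all(s.region == "utr3" for s in drawn)


def _records(distances, strand="+"):
    idx = 0
    out = []
    for d in distances:
        site = make_site(pos=10_000 + idx * 100_000)
        out.append(type("R", (), {})())
        rec = out[-1]
        rec.site, rec.alu_name = site, "a"
        rec.genomic_gap, rec.signed_distance = abs(d), d
        idx += 1
    return out


class TestHistogram:
    def test_hand_binned_signed_values(self):
        recs = _records([+50, +150, -50])
        res = distance_histogram(recs, HistogramSpec(window=2000, bin_width=10, signed=True))
        t = res.table
        assert t.loc[(t.bin_low == 41) & (t.bin_high == 50), "count"].item() == 1
        assert t.loc[(t.bin_low == 141) & (t.bin_high == 150), "count"].item() == 1
        assert t.loc[(t.bin_low == -50) & (t.bin_high == -41), "count"].item() == 1
        assert t["count"].sum() == 3 and res.n_excluded == 0

    def test_empty_input_all_zero_bins(self):
        res = distance_histogram([], HistogramSpec(window=1000, bin_width=100))
        assert res.table["count"].sum() == 0 and res.n_total == 0

    def test_proportions_sum_to_one_and_exclusions_counted(self):
        recs = _records([5, 500, 1500, 99_999])
        res = distance_histogram(recs, HistogramSpec(window=2000, bin_width=100))
        assert res.n_excluded == 1
        assert res.table["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        assert res.table["count"].sum() + res.n_excluded == 4


def exact_binomial_two_sided(k, n):
    """Sum of point probabilities <= P(k) — independent of scipy."""
    probs = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    return min(1.0, sum(p for p in probs if p <= probs[k] * (1 + 1e-12)))


class TestOrientation:
    def test_reported_fraction(self):
        recs = _records([+1] * 558 + [-1] * 442)
        out = orientation_test(recs)
        assert out["fraction_down"] == pytest.approx(0.558)
        assert out["n_down"] == 558 and out["n_up"] == 442

    def test_even_split_is_null(self):
        out = orientation_test(_records([+1] * 5 + [-1] * 5))
        assert out["fraction_down"] == 0.5 and out["p_value"] == pytest.approx(1.0)

    def test_p_matches_independent_exact_binomial(self):
        out = orientation_test(_records([+1] * 80 + [-1] * 20))
        assert out["p_value"] == pytest.approx(exact_binomial_two_sided(80, 100), rel=1e-9)

    def test_window_restriction_and_empty_error(self):
        recs = _records([+50, +3000])
        assert orientation_test(recs, max_distance=2000)["n_down"] == 1
        with pytest.raises(ValueError, match="no records"):
            orientation_test(_records([+3000]), max_distance=2000)


class TestDistanceComparison:
    def test_identical_samples_null_case(self):
        out = compare_distance_distributions([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_separated_samples_reject(self):
        rng = np.random.default_rng(0)
        obs = 100 + rng.normal(0, 1, 50)
        null = 10_000 + rng.normal(0, 1, 50)
        out = compare_distance_distributions(obs, null)
        assert out["p"] < 1e-10 and out["mean_obs"] < out["mean_null"]

    def test_swapping_arguments_negates_t_preserves_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.exponential(500, 80), rng.exponential(900, 60)
        fwd = compare_distance_distributions(a, b)
        rev = compare_distance_distributions(b, a)
        assert fwd["t"] == pytest.approx(-rev["t"])
        assert fwd["p"] == pytest.approx(rev["p"])


def test_vectorized_records_agree_with_scalar_calls(small_genome):
    from alu_cis_edit.simulate import SyntheticConfig, simulate_sites
    conf = SyntheticConfig(n_chroms=1, chrom_length=2_000_000, n_genes=10,
                           n_alu_pairs_per_gene=5, n_sites=50, seed=5)
    sites, _ = simulate_sites(conf, small_genome)
    sites = [s for s in sites if s.source != "alu"]
    idx = EditedAluIndex(small_genome.alus)
    vec = compute_distance_records(sites, idx, genes=small_genome.genes)
    from alu_cis_edit.proximity import resolve_gene_strands
    strands = resolve_gene_strands(sites, small_genome.genes)
    for s, strand, rec in zip(sites, strands, vec):
        one = nearest_edited_alu(s, idx, strand)
        assert (one is None) == (rec is None)
        if rec is not None:
            assert (one.genomic_gap, one.signed_distance) == \
                   (rec.genomic_gap, rec.signed_distance)
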