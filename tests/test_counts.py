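"""Two-resolution counting: cache builds, region queries, normalization."""

import numpy as np
import pandas as pd
import pysam
import pytest

import nascentq as nq
from nascentq import counts
from nascentq.errors import CacheVersionError, DataError

from conftest import make_cache, random_track, site_sum


def write_bam(path, reads, chrom_sizes={"chr1": 1_000_000}):
    """reads: list of (chrom, start, end, strand)."""
    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_sizes[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (chrom, start, end, strand) in enumerate(sorted(reads, key=lambda r: (tid[r[0]], r[1]))):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.flag = 16 if strand == "-" else 0
            a.mapping_quality = 60
            a.query_sequence = "A" * (end - start)
            a.cigarstring = f"{end - start}M"
            bam.write(a)
    return path


class TestBuildCache:
    def test_three_prime_sites_and_bins(self, tmp_path):
        """Plus-strand 3' ends at 150, 150, 410 -> sites {150:2, 410:1},
        bins {0:2, 2:1} with bin index = pos // 200."""
        reads = [
            ("chr1", 121, 151, "+"),
            ("chr1", 130, 151, "+"),
            ("chr1", 381, 411, "+"),
        ]
        cache = nq.build_cache(write_bam(tmp_path / "a.bam", reads))
        tr = cache.tracks[("chr1", "+")]
        assert dict(zip(tr.positions.tolist(), tr.site_counts.tolist())) == {150: 2, 410: 1}
        assert tr.bins[0] == 2 and tr.bins[2] == 1 and tr.bins[1] == 0
        assert cache.total_mapped == 3

    def test_minus_strand_three_prime_is_left_end(self, tmp_path):
        cache = nq.build_cache(write_bam(tmp_path / "a.bam", [("chr1", 500, 530, "-")]))
        tr = cache.tracks[("chr1", "-")]
        assert tr.positions.tolist() == [500]

    def test_five_prime_rule(self, tmp_path):
        path = write_bam(tmp_path / "a.bam", [("chr1", 500, 530, "+"), ("chr1", 600, 630, "-")])
        cache = nq.build_cache(path, read_rule="five_prime")
        assert cache.tracks[("chr1", "+")].positions.tolist() == [500]
        assert cache.tracks[("chr1", "-")].positions.tolist() == [629]

    def test_empty_bam_gives_empty_cache(self, tmp_path):
        cache = nq.build_cache(write_bam(tmp_path / "a.bam", []))
        assert cache.total_mapped == 0 and cache.tracks == {}

    def test_single_pass_over_alignments(self, tmp_path, monkeypatch):
        path = write_bam(tmp_path / "a.bam", [("chr1", 0, 30, "+")])
        opens = []
        real = pysam.AlignmentFile

        def counting(*args, **kwargs):
            opens.append(args[0])
            return real(*args, **kwargs)

        monkeypatch.setattr(counts.pysam, "AlignmentFile", counting)
        nq.build_cache(path)
        assert len(opens) == 1

    def test_unknown_read_rule_rejected(self, tmp_path):
        with pytest.raises(DataError):
            nq.build_cache(write_bam(tmp_path / "a.bam", []), read_rule="midpoint")


class TestBedgraphInput:
    def test_pair_matches_bam_from_same_sites(self, tmp_path):
        plus = tmp_path / "p.bg"
        minus = tmp_path / "m.bg"
        plus.write_text("chr1\t150\t151\t2\nchr1\t410\t411\t1\n")
        minus.write_text("chr1\t700\t701\t-3\n")  # negative convention
        cache = nq.build_cache((plus, minus))
        assert cache.total_mapped == 6
        assert cache.count("chr1", 0, 1000, "+") == 3
        assert cache.count("chr1", 0, 1000, "-") == 3

    def test_fractional_values_fatal_unless_allowed(self, tmp_path):
        plus = tmp_path / "p.bg"
        minus = tmp_path / "m.bg"
        plus.write_text("chr1\t10\t11\t1.5\n")
        minus.write_text("")
        with pytest.raises(DataError):
            nq.build_cache((plus, minus))
        cache = nq.build_cache((plus, minus), allow_noninteger=True)
        assert cache.total_mapped == 2  # 1.5 rounds to 2


class TestRegionCount:
    def test_small_example(self):
        cache = make_cache({("chr1", "+"): {100: 3, 105: 2, 300: 7}})
        assert cache.count("chr1", 100, 106, "+") == 5
        assert cache.count("chr1", 0, 10_000, "+") == 12  # conservation
        assert cache.count("chr2", 0, 100, "+") == 0  # unknown chrom
        assert cache.count("chr1", 50, 50, "+") == 0  # empty interval

    def test_orientation_rules(self):
        cache = make_cache({("chr1", "+"): {10: 1}, ("chr1", "-"): {10: 4}})
        q = nq.RegionQuery("chr1", 0, 100, "+", "sense")
        assert cache.region_count(q) == 1
        assert cache.region_count(nq.RegionQuery("chr1", 0, 100, "+", "antisense")) == 4
        assert cache.region_count(nq.RegionQuery("chr1", 0, 100, "+", "both")) == 5

    def test_thousand_random_queries_match_site_sum_oracle(self, rng):
        sites = random_track(rng, n_sites=500)
        cache = make_cache(sites)
        sitemap = sites[("chr1", "+")]
        for _ in range(1000):
            a, b = sorted(rng.integers(0, 100_100, size=2).tolist())
            assert cache.count("chr1", a, b, "+") == site_sum(sitemap, a, b)

    def test_ten_thousand_read_bam_matches_naive_membership(self, tmp_path, rng):
        reads = []
        for _ in range(10_000):
            start = int(rng.integers(0, 500_000))
            strand = "+" if rng.integers(2) else "-"
            reads.append(("chr1", start, start + 30, strand))
        cache = nq.build_cache(write_bam(tmp_path / "big.bam", reads))
        cache.validate()
        # naive oracle: representative base per read, interval membership
        rep = {"+": [], "-": []}
        for _, s, e, st in reads:
            rep[st].append(e - 1 if st == "+" else s)
        rep = {k: np.array(v) for k, v in rep.items()}
        for _ in range(100):
            a, b = sorted(rng.integers(0, 510_000, size=2).tolist())
            st = "+" if rng.integers(2) else "-"
            naive = int(((rep[st] >= a) & (rep[st] < b)).sum())
            assert cache.count("chr1", a, b, st) == naive


class TestCachePersistence:
    def test_round_trip_is_identical(self, tmp_path, rng):
        cache = make_cache(random_track(rng))
        path = tmp_path / "x.cache"
        cache.save(path)
        loaded = nq.CountCache.load(path)
        loaded.validate()
        assert loaded.total_mapped == cache.total_mapped
        for _ in range(50):
            a, b = sorted(rng.integers(0, 100_100, size=2).tolist())
            assert loaded.count("chr1", a, b, "+") == cache.count("chr1", a, b, "+")

    def test_version_mismatch_raises(self, tmp_path, rng):
        import pickle

        path = tmp_path / "x.cache"
        make_cache(random_track(rng)).save(path)
        payload = pickle.loads(path.read_bytes())
        payload["version"] = 999
        path.write_bytes(pickle.dumps(payload))
        with pytest.raises(CacheVersionError):
            nq.CountCache.load(path)

    def test_mixed_read_rules_refused(self, rng):
        c1 = make_cache(random_track(rng), read_rule="three_prime")
        c2 = make_cache(random_track(rng), read_rule="five_prime")
        with pytest.raises(DataError):
            counts.check_compatible([c1, c2])


class TestSizeFactors:
    def test_user_factors_returned_verbatim(self):
        mat = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        f = nq.size_factors(mat, [1.0, 2.0])
        assert f.tolist() == [1.0, 2.0]

    def test_identical_samples_get_equal_factors(self):
        mat = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        f = nq.size_factors(mat)
        assert f["a"] == pytest.approx(f["b"])
        assert f["a"] == pytest.approx(1.0)

    def test_doubled_sample_gets_double_factor(self):
        a = np.array([10, 23, 55, 100, 41])
        mat = pd.DataFrame({"a": a, "b": 2 * a})
        f = nq.size_factors(mat)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_all_zero_matrix_fatal(self):
        with pytest.raises(DataError):
            nq.size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))

    def test_zero_count_sample_fatal(self):
        with pytest.raises(DataError):
            nq.size_factors(pd.DataFrame({"a": [5, 5], "b": [0, 0]}))

    def test_negative_user_factor_fatal(self):
        with pytest.raises(DataError):
            nq.size_factors(pd.DataFrame({"a": [1], "b": [2]}), [1.0, -1.0])


class TestHypothesisProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    sites_strategy = st.dictionaries(
        st.integers(0, 5_000), st.integers(1, 5), min_size=0, max_size=80
    )
    interval_strategy = st.tuples(st.integers(0, 5_200), st.integers(0, 5_200))

    @given(sites=sites_strategy, iv=interval_strategy)
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_hybrid_query_equals_site_sum(self, sites, iv):
        """Bin+site hybrid answers match pure site summation for any
        track and interval, including bin-boundary-straddling ones."""
        cache = make_cache({("c", "+"): sites}) if sites else make_cache({})
        a, b = sorted(iv)
        assert cache.count("c", a, b, "+") == site_sum(sites, a, b)
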