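"""Interval overlap, background construction and conservation tests."""

from math import comb
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from promomethyl import (
    ValidationError,
    build_background_regions,
    conservation_compare,
    delta_phylop,
    make_site_table,
    merge_intervals,
    overlap_tfbs,
    read_bedgraph,
    read_wig,
    subtract_intervals,
    wilcoxon_rank_sum,
    write_bedgraph,
)
from promomethyl.simulate import simulate_conservation


def _intervals(rows):
    cols = ["chrom", "start", "end"] + (["name"] if rows and len(rows[0]) > 3 else [])
    return pd.DataFrame(rows, columns=cols)


def brute_force_overlap(sites, tfbs):
    """Quadratic oracle: 1-based pos in 0-based half-open [start, end)."""
    hits = set()
    for s in sites.itertuples():
        for t in tfbs.itertuples():
            if t.chrom == s.chrom and t.start < s.pos <= t.end:
                hits.add((s.chrom, s.pos))
    return hits


class TestOverlapTFBS:
    def _sites(self, positions, chrom="chr1"):
        return make_site_table([(chrom, p, "r1") for p in positions])

    def test_inside(self):
        out = overlap_tfbs(self._sites([100]), _intervals([("chr1", 90, 110)]))
        assert out.attrs["n_sites_with_tfbs"] == 1

    def test_boundary_convention(self):
        """1-based pos p lies in 0-based half-open [s,e) iff s < p <= e:
        pos=110 is the last base of [90,110); pos=111 is outside."""
        out = overlap_tfbs(self._sites([110]), _intervals([("chr1", 90, 110)]))
        assert out.attrs["n_sites_with_tfbs"] == 1
        out = overlap_tfbs(self._sites([111]), _intervals([("chr1", 90, 110)]))
        assert out.attrs["n_sites_with_tfbs"] == 0

    def test_start_boundary_included(self):
        # pos=91 is base 90 in 0-based: the first base of [90,110)
        out = overlap_tfbs(self._sites([91]), _intervals([("chr1", 90, 110)]))
        assert out.attrs["n_sites_with_tfbs"] == 1

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValidationError):
            overlap_tfbs(self._sites([5]), _intervals([("chr1", 10, 10)]))

    def test_matches_brute_force_large(self):
        rng = np.random.default_rng(0)
        sites = self._sites(sorted(rng.choice(np.arange(1, 10_000), 200, replace=False)))
        tf = _intervals(
            [("chr1", int(s), int(s) + int(w))
             for s, w in zip(rng.integers(0, 10_000, 500), rng.integers(1, 60, 500))]
        )
        out = overlap_tfbs(sites, tf)
        hit = set(
            out.dropna(subset=["tfbs_start"])[["chrom", "pos"]]
            .itertuples(index=False, name=None)
        )
        assert hit == brute_force_overlap(sites, tf)
        assert out.attrs["n_sites_with_tfbs"] == len(brute_force_overlap(sites, tf))

    @settings(max_examples=40, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_property(self, data):
        n_sites = data.draw(st.integers(1, 15))
        n_iv = data.draw(st.integers(0, 15))
        pos = data.draw(
            st.lists(st.integers(1, 200), min_size=n_sites, max_size=n_sites,
                     unique=True)
        )
        sites = self._sites(sorted(pos))
        ivs = [
            (
                "chr1",
                s := data.draw(st.integers(0, 200)),
                s + data.draw(st.integers(1, 40)),
            )
            for _ in range(n_iv)
        ]
        tf = _intervals(ivs) if ivs else pd.DataFrame(
            columns=["chrom", "start", "end"]
        )
        out = overlap_tfbs(sites, tf)
        hit = set(
            out.dropna(subset=["tfbs_start"])[["chrom", "pos"]]
            .itertuples(index=False, name=None)
        ) if "tfbs_start" in out.columns else set()
        assert hit == brute_force_overlap(sites, tf)


class TestIntervalArithmetic:
    def test_merge(self):
        out = merge_intervals(_intervals([("chr1", 0, 10), ("chr1", 5, 20),
                                          ("chr1", 30, 40)]))
        assert list(out.itertuples(index=False, name=None)) == [
            ("chr1", 0, 20), ("chr1", 30, 40)
        ]

    def test_subtract_splits(self):
        out = subtract_intervals(
            _intervals([("chr1", 0, 100)]), _intervals([("chr1", 40, 60)])
        )
        assert list(out.itertuples(index=False, name=None)) == [
            ("chr1", 0, 40), ("chr1", 60, 100)
        ]

    def test_subtract_total(self):
        out = subtract_intervals(
            _intervals([("chr1", 10, 20)]), _intervals([("chr1", 0, 50)])
        )
        assert out.empty

    @settings(max_examples=40, derandomize=True)
    @given(st.data())
    def test_subtract_matches_per_base_oracle(self, data):
        a = [("chr1", s := data.draw(st.integers(0, 80)),
              s + data.draw(st.integers(1, 30)))
             for _ in range(data.draw(st.integers(1, 4)))]
        b = [("chr1", s := data.draw(st.integers(0, 80)),
              s + data.draw(st.integers(1, 30)))
             for _ in range(data.draw(st.integers(0, 4)))]
        out = subtract_intervals(_intervals(a), _intervals(b))
        covered = set()
        for _, s, e in out.itertuples(index=False, name=None):
            covered |= set(range(s, e))
        base_a = set()
        for _, s, e in a:
            base_a |= set(range(s, e))
        base_b = set()
        for _, s, e in b:
            base_b |= set(range(s, e))
        assert covered == base_a - base_b


class TestBackgroundRegions:
    def _expr(self):
        # target IQR over samples 10..90 -> [30, 70]
        rows = [("ER", f"s{i}", v) for i, v in enumerate([10, 30, 50, 70, 90])]
        rows += [("inA", "s0", 50), ("inB", "s0", 30), ("outA", "s0", 100),
                 ("outB", "s0", 5)]
        return pd.DataFrame(rows, columns=["gene_id", "sample", "expression"])

    def _cpgs(self, positions):
        return pd.DataFrame({"chrom": "chr1", "pos": positions})

    def test_toy_genome_oracle(self):
        """Hand-computed: inA exon [2000,2200) pads to [1250,2950); CDS
        [2800,3000) leaves [1250,2800) = 1550 bp with 5 CpGs -> kept.
        inB exon [9000,9100) pads to [8250,9850); CDS covers all -> dropped.
        outA/outB excluded by expression."""
        exons = pd.DataFrame(
            [("chr1", 2000, 2200, "inA"), ("chr1", 9000, 9100, "inB"),
             ("chr1", 5000, 5100, "outA")],
            columns=["chrom", "start", "end", "gene_id"],
        )
        cds = _intervals([("chr1", 2800, 3000), ("chr1", 8000, 10_000)])
        cpgs = self._cpgs([1300, 1500, 2000, 2500, 2799, 2900, 9000])
        out = build_background_regions(
            self._expr(), "ER", exons, cds, cpgs
        )
        assert list(out[["chrom", "start", "end", "gene_id", "n_cpg"]]
                    .itertuples(index=False, name=None)) == [
            ("chr1", 1250, 2800, "inA", 5)
        ]
        assert out.attrs["iqr"] == (30.0, 70.0)

    def test_length_boundary_strict(self):
        """Fragment of exactly min_len bp is dropped (strictly longer kept)."""
        exons = pd.DataFrame([("chr1", 1000, 1400, "inA")],
                             columns=["chrom", "start", "end", "gene_id"])
        # pad 0 to control length exactly
        out = build_background_regions(
            self._expr(), "ER", exons, _intervals([]),
            self._cpgs([1050, 1100, 1150, 1200]), pad_bp=0, min_len=400,
        )
        assert out.empty

    def test_min_cpg_inclusive(self):
        exons = pd.DataFrame([("chr1", 1000, 1500, "inA")],
                             columns=["chrom", "start", "end", "gene_id"])
        kw = dict(pad_bp=0, min_len=400, min_cpg=4)
        ok = build_background_regions(
            self._expr(), "ER", exons, _intervals([]),
            self._cpgs([1050, 1100, 1150, 1200]), **kw
        )
        assert len(ok) == 1 and ok["n_cpg"].iloc[0] == 4
        short = build_background_regions(
            self._expr(), "ER", exons, _intervals([]),
            self._cpgs([1050, 1100, 1150]), **kw
        )
        assert short.empty

    def test_missing_target_gene(self):
        with pytest.raises(ValidationError):
            build_background_regions(
                self._expr(), "nope",
                pd.DataFrame(columns=["chrom", "start", "end", "gene_id"]),
                _intervals([]), self._cpgs([]),
            )

    def test_output_never_overlaps_cds(self):
        rng = np.random.default_rng(1)
        exons = pd.DataFrame(
            [("chr1", int(s), int(s) + 300, "inA") for s in
             rng.integers(0, 50_000, 5)],
            columns=["chrom", "start", "end", "gene_id"],
        )
        cds = _intervals(
            [("chr1", int(s), int(s) + int(w)) for s, w in
             zip(rng.integers(0, 50_000, 10), rng.integers(50, 2000, 10))]
        )
        cpgs = self._cpgs(sorted(rng.choice(np.arange(1, 52_000), 800,
                                            replace=False)))
        out = build_background_regions(self._expr(), "ER", exons, cds, cpgs,
                                       min_len=100, min_cpg=1)
        for f in out.itertuples():
            for c in cds.itertuples():
                assert f.end <= c.start or f.start >= c.end


class TestWilcoxon:
    def test_hand_enumeration_example(self):
        """A={1,2}, B={3,4}: rank-sum of A is 3, exact two-sided p=1/3."""
        w, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert w == 3.0 and p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 4), (4, 5), (5, 5)])
    def test_exact_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        a = rng.normal(size=n1)
        b = rng.normal(size=n2)
        _, p = wilcoxon_rank_sum(a, b)
        # independent enumeration of the rank-sum distribution
        ranks = stats.rankdata(np.concatenate([a, b]))
        w_obs = ranks[:n1].sum()
        dist = [sum(c) for c in combinations(ranks, n1)]
        lo = sum(1 for d in dist if d <= w_obs) / comb(n1 + n2, n1)
        hi = sum(1 for d in dist if d >= w_obs) / comb(n1 + n2, n1)
        p_exact = min(1.0, 2 * min(lo, hi))
        assert p == pytest.approx(p_exact)

    def test_normal_approx_close_to_exact_at_n10(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        _, p_exact = wilcoxon_rank_sum(a, b)  # n=10 tie-free -> exact
        _, p_norm = wilcoxon_rank_sum(a, b, exact_n_max=0)  # force asymptotic
        assert abs(p_exact - p_norm) < 1e-3 * 35  # continuity-corrected approx

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


def _region_frame():
    return pd.DataFrame(
        [("chr1", 0, 100, "rA"), ("chr1", 200, 300, "rB")],
        columns=["chrom", "start", "end", "region_id"],
    )


class TestConservationCompare:
    def test_power_under_depression(self):
        """With a 2-sigma CpG depression, the pooled test rejects at
        alpha=0.001 in >=95% of seeds."""
        regions = pd.DataFrame([("chr1", 0, 2200, "rA")],
                               columns=["chrom", "start", "end", "region_id"])
        cpgs = {"rA": list(range(1, 2201, 11))[:200]}
        rejected = 0
        n_seeds = 100
        for seed in range(n_seeds):
            track = simulate_conservation(regions, cpgs, 0.5, 2.0, seed=seed)
            res = conservation_compare(track, regions, cpgs)
            rejected += res["p_value"] < 0.001
        assert rejected >= 0.95 * n_seeds

    def test_empty_group_rejected(self):
        regions = _region_frame()
        track = simulate_conservation(regions, {}, 0.5, 0.0, seed=0)
        with pytest.raises(ValidationError):
            conservation_compare(track, regions, {})

    def test_stratified_mode_reports_per_region(self):
        regions = _region_frame()
        cpgs = {"rA": [10, 20], "rB": [210, 220]}
        track = simulate_conservation(regions, cpgs, 0.5, 1.0, seed=2)
        res = conservation_compare(track, regions, cpgs, mode="stratified")
        assert set(res["stratified"]["region_id"]) == {"rA", "rB"}


class TestDeltaPhylop:
    def test_simple_delta(self):
        """Scores {0.2, 0.4, 0.6} with C at the 0.2 position -> delta -0.2."""
        regions = pd.DataFrame([("chr1", 0, 3, "rA")],
                               columns=["chrom", "start", "end", "region_id"])
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": [1, 2, 3], "score": [0.2, 0.4, 0.6]}
        )
        res = delta_phylop(track, regions, {"rA": [1]})
        assert res["cpg_delta"]["delta"].iloc[0] == pytest.approx(-0.2)

    def test_constant_region_all_zero(self):
        regions = pd.DataFrame([("chr1", 0, 5, "rA")],
                               columns=["chrom", "start", "end", "region_id"])
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": range(1, 6), "score": 1.5}
        )
        res = delta_phylop(track, regions, {"rA": [2]})
        assert (res["positions"]["delta"] == 0).all()

    def test_region_means_zero(self):
        regions = _region_frame()
        cpgs = {"rA": [10, 20], "rB": [250]}
        track = simulate_conservation(regions, cpgs, 0.3, 1.0, seed=9)
        res = delta_phylop(track, regions, cpgs)
        means = res["positions"].groupby("region_id")["delta"].mean()
        assert (means.abs() < 1e-9).all()


class TestTrackIO:
    def test_bedgraph_roundtrip(self, tmp_path):
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": [5, 6, 7], "score": [0.5, -1.25, 3.0]}
        )
        p = tmp_path / "t.bedGraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p)
        pd.testing.assert_frame_equal(back, track)

    def test_bedgraph_interval_expansion(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t3\t1.5\n")
        back = read_bedgraph(p)
        assert list(back["pos"]) == [1, 2, 3]
        assert (back["score"] == 1.5).all()

    def test_wig_fixed_and_variable_step(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text(
            "fixedStep chrom=chr1 start=10 step=2\n0.1\n0.2\n"
            "variableStep chrom=chr2\n5 1.0\n9 2.0\n"
        )
        back = read_wig(p)
        assert list(back[back.chrom == "chr1"]["pos"]) == [10, 12]
        assert list(back[back.chrom == "chr2"]["pos"]) == [5, 9]
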