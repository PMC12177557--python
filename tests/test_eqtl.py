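import numpy as np
import pandas as pd
import pytest

from bloodeqtl.eqtl import (
    call_all_regions,
    call_regions,
    classify_cis_trans,
    detect_hotspots,
    detect_top_hotspots,
    overlap_intervals,
)

from oracles import overlap_oracle, region_oracle


def records(positions, pvals=None, gene="g1", chrom="1"):
    pvals = pvals if pvals is not None else [1e-8] * len(positions)
    return pd.DataFrame(
        {
            "gene": gene,
            "id": [f"v{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "p": pvals,
        }
    )


class TestCallRegions:
    def test_small_clusters_discarded(self):
        out = call_regions(records([1_000_000, 1_500_000, 3_000_000]))
        assert out == []

    def test_single_region_core_and_extension(self):
        out = call_regions(records([1_000_000, 1_400_000, 1_900_000]))
        assert len(out) == 1
        r = out[0]
        assert (r["core_start"], r["core_end"]) == (1_000_000, 1_900_000)
        assert (r["ext_start"], r["ext_end"]) == (500_000, 2_400_000)

    def test_gap_of_exactly_1mb_splits(self):
        # 'less than 1 Mb apart' means a 1,000,000 bp gap starts a new cluster
        pos = [100, 200, 300, 1_000_300, 1_000_400, 1_000_500]
        out = call_regions(records(pos))
        assert len(out) == 2
        assert out[0]["core_end"] == 300
        assert out[1]["core_start"] == 1_000_300

    def test_extension_floored_at_one(self):
        out = call_regions(records([1000, 2000, 3000]))
        assert out[0]["ext_start"] == 1

    def test_top_variant_tie_broken_by_position(self):
        out = call_regions(records([100, 200, 300], [1e-9, 1e-9, 1e-12]))
        assert out[0]["top_variant"] == "v2"
        out = call_regions(records([100, 200, 300], [1e-9, 1e-9, 1e-9]))
        assert out[0]["top_variant"] == "v0"

    def test_multi_gene_rejected(self):
        df = pd.concat([records([100]), records([200], gene="g2")])
        with pytest.raises(ValueError, match="single gene"):
            call_regions(df)

    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(120):
            n = rng.integers(1, 30)
            pos = sorted(rng.integers(1, 20_000_000, size=n).tolist())
            pv = rng.uniform(1e-12, 1e-7, size=n).tolist()
            out = call_regions(records(pos, pv))
            ref = region_oracle(pos, pv)
            assert len(out) == len(ref)
            for a, b in zip(out, ref):
                assert a["core_start"] == b["core_start"]
                assert a["core_end"] == b["core_end"]
                assert a["ext_start"] == b["ext_start"]
                assert a["ext_end"] == b["ext_end"]
                assert a["n_snps"] == b["n_snps"]
                assert a["top_variant"] == f"v{b['top_idx']}"

    def test_region_count_monotonicity(self, rng):
        pos = sorted(rng.integers(1, 30_000_000, size=60).tolist())
        pv = [1e-8] * 60
        n3 = len(call_regions(records(pos, pv), min_snps=3))
        n5 = len(call_regions(records(pos, pv), min_snps=5))
        assert n5 <= n3
        g1 = len(call_regions(records(pos, pv), gap=500_000))
        g2 = len(call_regions(records(pos, pv), gap=2_000_000))
        assert g2 <= g1  # larger gap merges clusters


class TestCisTrans:
    def test_upstream_within_window_is_cis(self):
        assert classify_cis_trans("1", 500_000, "1", 1_000_000, 1_050_000) == "cis"

    def test_other_chromosome_is_trans(self):
        assert classify_cis_trans("2", 1_000_000, "1", 1_000_000, 1_050_000) == "trans"

    def test_exactly_1mb_is_cis_inclusive(self):
        assert classify_cis_trans("1", 1, "1", 1_000_001, 1_000_100) == "cis"
        assert classify_cis_trans("1", 1, "1", 1_000_002, 1_000_100) == "trans"

    def test_inside_gene_is_cis(self):
        assert classify_cis_trans("1", 1_025_000, "1", 1_000_000, 1_050_000) == "cis"


class TestHotspots:
    def make_sig(self, n_genes, vid="hot1", chrom="1", pos=5_000_000):
        return pd.DataFrame(
            {
                "phenotype": [f"g{i}" for i in range(n_genes)],
                "id": vid,
                "chrom": chrom,
                "pos": pos,
            }
        )

    def test_ten_genes_is_hotspot_nine_is_not(self):
        assert len(detect_hotspots(self.make_sig(10))) == 1
        assert len(detect_hotspots(self.make_sig(9))) == 0

    def test_empty_input(self):
        out = detect_hotspots(pd.DataFrame(columns=["phenotype", "id", "chrom", "pos"]))
        assert out.empty

    def test_duplicate_gene_variant_pairs_counted_once(self):
        sig = pd.concat([self.make_sig(9), self.make_sig(9)])
        assert len(detect_hotspots(sig)) == 0

    def test_nested_thresholds(self, rng):
        sigs = []
        for v in range(6):
            k = rng.integers(5, 20)
            sigs.append(self.make_sig(int(k), vid=f"hot{v}", pos=int(1e6 * (v + 1))))
        sig = pd.concat(sigs)
        at10 = set(detect_hotspots(sig, min_genes=10)["id"])
        at11 = set(detect_hotspots(sig, min_genes=11)["id"])
        assert at11 <= at10


class TestTopHotspots:
    def make_regions(self, tops):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(tops))],
                "chrom": "1",
                "core_start": 1,
                "core_end": 2,
                "ext_start": 1,
                "ext_end": 2,
                "n_snps": 3,
                "top_variant": tops,
                "top_p": 1e-9,
                "label": "trans",
            }
        )

    def test_top_in_ten_regions(self):
        out = detect_top_hotspots(self.make_regions(["v1"] * 10 + ["v2"] * 3))
        assert out["id"].tolist() == ["v1"]
        assert out["n_top_regions"].iloc[0] == 10

    def test_all_distinct_tops_none(self):
        out = detect_top_hotspots(self.make_regions([f"v{i}" for i in range(12)]))
        assert out.empty

    def test_counts_match_recount_under_tie_break(self, rng):
        # regions built from records with p ties resolved by position
        sig_frames = []
        for gi in range(12):
            pos = [100 + gi, 200 + gi, 300 + gi]
            df = pd.DataFrame(
                {"gene": f"g{gi}", "id": [f"s{p}" for p in pos], "chrom": "1",
                 "pos": pos, "p": [1e-9, 1e-9, 1e-9]}
            )
            sig_frames.append(df)
        regions = []
        for df in sig_frames:
            regions.extend(call_regions(df))
        regions = pd.DataFrame(regions).rename(columns={})
        # brute-force recount: top = min(p, then pos)
        expected = {}
        for df in sig_frames:
            top = df.sort_values(["p", "pos"]).iloc[0]["id"]
            expected[top] = expected.get(top, 0) + 1
        out = detect_top_hotspots(regions, min_top=1)
        got = dict(zip(out["id"], out["n_top_regions"]))
        assert got == expected


class TestOverlap:
    def make(self, intervals, cols=("trait", "chrom", "start", "end")):
        return pd.DataFrame([dict(zip(cols, iv)) for iv in intervals])

    def regions_df(self, intervals):
        rows = []
        for name, chrom, s, e in intervals:
            rows.append(
                {"gene": name, "chrom": chrom, "core_start": s, "core_end": e,
                 "ext_start": s, "ext_end": e, "n_snps": 3, "top_variant": "v",
                 "top_p": 1e-9, "label": "cis"}
            )
        return pd.DataFrame(rows)

    def test_basic_overlap(self):
        q = self.make([("t1", "1", 10_000_000, 20_000_000)])
        r = self.regions_df([("g1", "1", 15_000_000, 25_000_000)])
        assert len(overlap_intervals(q, r)) == 1

    def test_different_chromosome_no_overlap(self):
        q = self.make([("t1", "2", 10_000_000, 20_000_000)])
        r = self.regions_df([("g1", "1", 15_000_000, 25_000_000)])
        assert overlap_intervals(q, r).empty

    def test_single_shared_bp_counts(self):
        q = self.make([("t1", "1", 100, 200)])
        r = self.regions_df([("g1", "1", 200, 300)])
        assert len(overlap_intervals(q, r)) == 1

    def test_malformed_interval_rejected(self):
        q = self.make([("t1", "1", 200, 100)])
        r = self.regions_df([("g1", "1", 1, 2)])
        with pytest.raises(ValueError, match="malformed"):
            overlap_intervals(q, r)

    def test_matches_quadratic_brute_force(self, rng):
        for trial in range(20):
            qtls = [
                (f"t{i}", str(rng.integers(1, 4)), int(s), int(s + rng.integers(1, 5_000_000)))
                for i, s in enumerate(rng.integers(1, 50_000_000, size=25))
            ]
            regs = [
                (f"g{i}", str(rng.integers(1, 4)), int(s), int(s + rng.integers(1, 5_000_000)))
                for i, s in enumerate(rng.integers(1, 50_000_000, size=25))
            ]
            got = overlap_intervals(self.make(qtls), self.regions_df(regs))
            pairs = set(zip(got["trait"], got["gene"]))
            assert pairs == overlap_oracle(qtls, regs)


def test_call_all_regions_labels(rng):
    genes = pd.DataFrame(
        {"gene": ["gA", "gB"], "chrom": ["1", "1"], "start": [2_000_000, 30_000_000],
         "end": [2_050_000, 30_050_000]}
    )
    sig = pd.DataFrame(
        {
            "phenotype": ["gA"] * 3 + ["gB"] * 3,
            "id": [f"v{i}" for i in range(6)],
            "chrom": "1",
            "pos": [1_500_000, 1_600_000, 1_700_000, 1_500_000, 1_600_000, 1_700_000],
            "p": [1e-9] * 6,
        }
    )
    out = call_all_regions(sig, genes)
    lab = dict(zip(out["gene"], out["label"]))
    assert lab == {"gA": "cis", "gB": "trans"}
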