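import numpy as np
import pandas as pd
import pytest

from fetalmeth.annotation import (CGI_CLASSES, GENIC_CLASSES, annotate,
                                  classify_cgi, classify_genic,
                                  median_by_feature,
                                  methylation_class_fractions)
from fetalmeth.io import IntervalTrack

from conftest import exact_beta


def make_manifest(positions, chrom="chr1"):
    return pd.DataFrame({"probe_id": [f"p{i}" for i in range(len(positions))],
                         "chrom": chrom, "pos": list(positions)})


def cgi_track(intervals):
    return IntervalTrack("cgis", pd.DataFrame(
        [(c, s, e, "CGI") for c, s, e in intervals],
        columns=["chrom", "start", "end", "label"]))


class TestClassifyCgi:
    def test_boundary_distances_around_single_island(self):
        # island covers 1-based 10001..12000
        track = cgi_track([("chr1", 10_000, 12_000)])
        cases = {
            11_000: "CGI",     # inside
            12_000: "CGI",     # last covered base
            12_001: "SHO",     # distance 1
            14_000: "SHO",     # exactly 2,000 -> shore (inclusive)
            14_001: "SHE",
            14_500: "SHE",     # 2,500 from the edge
            16_000: "SHE",     # exactly 4,000 -> shelf
            16_001: "NC",
            16_500: "NC",      # 4,500 from the edge
            10_000: "SHO",     # 1 bp left of the first covered base
            8_001: "SHO",      # 2,000 left
            8_000: "SHE",
        }
        manifest = make_manifest(sorted(cases))
        got = classify_cgi(manifest, track)
        for pos, expected in cases.items():
            pid = manifest.loc[manifest["pos"] == pos, "probe_id"].iloc[0]
            assert got[pid] == expected, (pos, got[pid], expected)

    def test_empty_track_gives_all_nc(self):
        manifest = make_manifest([100, 5_000])
        got = classify_cgi(manifest, IntervalTrack("cgis"))
        assert (got == "NC").all()

    def test_agrees_with_brute_force_distance_scan(self, rng):
        # random islands, exhaustive check against direct distance computation
        for _ in range(10):
            starts = np.sort(rng.choice(500_000, size=50, replace=False))
            islands = [("chr1", int(s), int(s + rng.integers(200, 3_000)))
                       for s in starts]
            track = cgi_track(islands)
            merged = track.merged().intervals
            positions = np.sort(rng.choice(600_000, size=1_000, replace=False)) + 1
            manifest = make_manifest(positions)
            got = classify_cgi(manifest, track)
            for pid, pos in zip(manifest["probe_id"], manifest["pos"]):
                dists = []
                inside = False
                for row in merged.itertuples():
                    if row.start < pos <= row.end:
                        inside = True
                    elif pos <= row.start:
                        dists.append(row.start + 1 - pos)
                    else:
                        dists.append(pos - row.end)
                if inside:
                    expected = "CGI"
                else:
                    d = min(dists)
                    expected = ("SHO" if d <= 2_000 else
                                "SHE" if d <= 4_000 else "NC")
                assert got[pid] == expected

    def test_partition_property(self, small_data):
        got = classify_cgi(small_data.manifest, small_data.cgis)
        assert got.isin(CGI_CLASSES).all()
        assert got.value_counts().sum() == len(small_data.manifest)


def make_genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                       "tx_start", "tx_end"])


class TestClassifyGenic:
    def test_plus_strand_promoter_windows(self):
        genes = make_genes([("g1", "chr1", "+", 100_000, 130_000)])
        cases = {99_000: "PP", 98_500: "PP", 100_500: "PP",
                 95_000: "DP", 90_000: "DP", 98_499: "DP",
                 100_501: "GB", 130_000: "GB",
                 130_001: "DS", 135_000: "DS",
                 135_001: "IG", 89_999: "IG"}
        manifest = make_manifest(sorted(cases))
        got = classify_genic(manifest, genes)
        for pos, expected in cases.items():
            pid = manifest.loc[manifest["pos"] == pos, "probe_id"].iloc[0]
            assert got[pid] == expected, (pos, got[pid], expected)

    def test_minus_strand_reflects_windows(self):
        # TSS at tx_end; upstream is genomically rightward
        genes = make_genes([("g1", "chr1", "-", 50_000, 60_000)])
        cases = {60_800: "PP", 59_500: "PP", 61_500: "PP",
                 61_501: "DP", 70_000: "DP",
                 59_499: "GB", 50_000: "GB",
                 49_999: "DS", 45_000: "DS",
                 44_999: "IG"}
        manifest = make_manifest(sorted(cases))
        got = classify_genic(manifest, genes)
        for pos, expected in cases.items():
            pid = manifest.loc[manifest["pos"] == pos, "probe_id"].iloc[0]
            assert got[pid] == expected, (pos, got[pid], expected)

    def test_precedence_pp_beats_gb(self):
        # probe in g1's body and g2's proximal promoter -> PP
        genes = make_genes([("g1", "chr1", "+", 10_000, 80_000),
                            ("g2", "chr1", "+", 51_000, 90_000)])
        manifest = make_manifest([50_500])
        assert classify_genic(manifest, genes)["p0"] == "PP"

    def test_translation_invariance(self, rng):
        genes = make_genes([("g1", "chr1", "+", 100_000, 120_000),
                            ("g2", "chr1", "-", 300_000, 340_000)])
        positions = np.sort(rng.choice(400_000, size=300, replace=False)) + 50_000
        manifest = make_manifest(positions)
        base = classify_genic(manifest, genes)
        shift = 1_000_000
        genes2 = genes.assign(tx_start=genes["tx_start"] + shift,
                              tx_end=genes["tx_end"] + shift)
        manifest2 = make_manifest(positions + shift)
        shifted = classify_genic(manifest2, genes2)
        assert (base.to_numpy() == shifted.to_numpy()).all()

    def test_strand_flip_reflection_invariance(self, rng):
        genes = make_genes([("g1", "chr1", "+", 100_000, 120_000)])
        positions = np.sort(rng.choice(200_000, size=300, replace=False)) + 30_000
        manifest = make_manifest(positions)
        base = classify_genic(manifest, genes)
        c = 2_000_000  # reflect x -> c - x and flip strand
        genes_r = make_genes([("g1", "chr1", "-", c - 120_000, c - 100_000)])
        manifest_r = make_manifest(np.sort(c - positions))
        reflected = classify_genic(manifest_r, genes_r)
        # match probes by reflected coordinate
        ref_by_pos = dict(zip(manifest_r["pos"],
                              reflected[manifest_r["probe_id"]].to_numpy()))
        for pos, cls in zip(manifest["pos"], base[manifest["probe_id"]]):
            assert ref_by_pos[c - pos] == cls

    def test_brute_force_window_scan(self, rng):
        genes = make_genes([
            (f"g{i}", "chr1", rng.choice(["+", "-"]),
             int(s), int(s + rng.integers(2_000, 30_000)))
            for i, s in enumerate(np.sort(rng.choice(900_000, 20)) + 50_000)])
        positions = np.sort(rng.choice(1_000_000, size=1_000, replace=False)) + 1
        manifest = make_manifest(positions)
        got = classify_genic(manifest, genes)

        def windows(g):
            if g.strand == "+":
                tss, tes = g.tx_start, g.tx_end
                return {"PP": (tss - 1_500, tss + 500),
                        "DP": (tss - 10_000, tss - 1_501),
                        "GB": (tss + 501, tes),
                        "DS": (tes + 1, tes + 5_000)}
            tss, tes = g.tx_end, g.tx_start
            return {"PP": (tss - 500, tss + 1_500),
                    "DP": (tss + 1_501, tss + 10_000),
                    "GB": (tes, tss - 501),
                    "DS": (tes - 5_000, tes - 1)}

        for pid, pos in zip(manifest["probe_id"], manifest["pos"]):
            expected = "IG"
            for cls in ("PP", "DP", "GB", "DS"):
                if any(lo <= pos <= hi for lo, hi in
                       (windows(g)[cls] for g in genes.itertuples())):
                    expected = cls
                    break
            assert got[pid] == expected, (pos, got[pid], expected)

    def test_partition_property(self, small_data):
        got = classify_genic(small_data.manifest, small_data.genes)
        assert got.isin(GENIC_CLASSES).all()
        assert got.value_counts().sum() == len(small_data.manifest)


class TestSummaries:
    def test_constant_betas_give_constant_medians(self):
        probe_ids = ["p0", "p1", "p2"]
        beta, meta = exact_beta(
            {"s1": [0.5] * 3, "s2": [0.5] * 3},
            probe_ids,
            [("s1", "muscle", 9, 1), ("s2", "muscle", 18, 1)])
        labels = pd.DataFrame({"cgi_class": ["CGI", "NC", "SHO"],
                               "genic_class": ["PP", "GB", "IG"]},
                              index=pd.Index(probe_ids, name="probe_id"))
        med = median_by_feature(beta, meta, labels)
        filled = med["median_beta"].dropna()
        assert len(filled) == 6  # 3 features x 2 groups
        assert (filled == 0.5).all()

    def test_single_feature_median(self):
        probe_ids = ["p0", "p1", "p2"]
        beta, meta = exact_beta({"s1": [0.1, 0.2, 0.9]}, probe_ids,
                                [("s1", "muscle", 9, 1)])
        labels = pd.DataFrame({"cgi_class": ["CGI"] * 3,
                               "genic_class": ["PP"] * 3},
                              index=pd.Index(probe_ids, name="probe_id"))
        med = median_by_feature(beta, meta, labels)
        val = med.query("cgi_class == 'CGI' and genic_class == 'PP'")
        assert val["median_beta"].iloc[0] == pytest.approx(0.2)
        # empty features come back missing, not zero
        assert med.query("cgi_class == 'NC'")["median_beta"].isna().all()

    def test_class_fractions_examples(self):
        beta, meta = exact_beta({"s1": [0.1, 0.5, 0.9]}, ["p0", "p1", "p2"],
                                [("s1", "muscle", 9, 1)])
        frac = methylation_class_fractions(beta, meta)
        row = frac.iloc[0]
        assert (row[["hypo", "intermediate", "hyper"]].to_numpy()
                == pytest.approx([1 / 3, 1 / 3, 1 / 3]))
        beta0, meta0 = exact_beta({"s1": [0.0, 0.0]}, ["p0", "p1"],
                                  [("s1", "muscle", 9, 1)])
        row0 = methylation_class_fractions(beta0, meta0).iloc[0]
        assert row0[["hypo", "intermediate", "hyper"]].tolist() == [1, 0, 0]

    def test_class_fractions_uniform(self, rng):
        vals = rng.random(100_000)
        beta, meta = exact_beta({"s1": vals}, [f"p{i}" for i in range(len(vals))],
                                [("s1", "muscle", 9, 1)])
        row = methylation_class_fractions(beta, meta).iloc[0]
        assert row["hypo"] == pytest.approx(0.25, abs=0.01)
        assert row["intermediate"] == pytest.approx(0.50, abs=0.01)
        assert row["hyper"] == pytest.approx(0.25, abs=0.01)
        assert row[["hypo", "intermediate", "hyper"]].sum() == pytest.approx(1.0)

    def test_annotate_combines_both_axes(self, small_data):
        labels = annotate(small_data.manifest, small_data.cgis,
                          small_data.genes)
        assert set(labels.columns) == {"cgi_class", "genic_class"}
        assert len(labels) == len(small_data.manifest)
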