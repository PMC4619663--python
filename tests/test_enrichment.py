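import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from fetalmeth.enrichment import (chromatin_state_enrichment, enrichment_or,
                                  nearest_gene, probe_state_labels,
                                  region_metaprofile, regions_to_items)
from fetalmeth.io import IntervalTrack, ValidationError
from fetalmeth.regions import Region


def labelled_probes(categories):
    idx = pd.Index([f"p{i}" for i in range(len(categories))], name="probe_id")
    return pd.Series(categories, index=idx)


def build_sets(a, b, c, d, cat="X", other="Y"):
    """Background of c+d probes, called subset of a+b, with a of the called
    and c of the background in category ``cat``."""
    labels = labelled_probes([cat] * c + [other] * d)
    called = labels.index[:a].append(labels.index[c:c + b])
    return called, labels.index, labels


class TestOddsRatio:
    def test_equal_proportions_gives_or_one(self):
        called, background, labels = build_sets(10, 90, 10, 90)
        # called must be subset of background; construct directly
        res = {r.category: r for r in enrichment_or(called, background, labels)}
        assert res["X"].odds_ratio == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        from fetalmeth.enrichment import odds_ratio_2x2
        assert odds_ratio_2x2(10, 90, 10, 90) == pytest.approx(1.0)
        assert odds_ratio_2x2(20, 80, 10, 90) == pytest.approx(2.25)
        assert odds_ratio_2x2(0, 100, 50, 50) == pytest.approx(
            (0.5 * 50.5) / (100.5 * 50.5))

    def test_counts_and_or_from_explicit_construction(self):
        # 200 background probes: 30 in category X; called = 20 of the X
        # probes plus 80 of the Y probes
        labels = labelled_probes(["X"] * 30 + ["Y"] * 170)
        called = labels.index[:20].append(labels.index[30:110])
        res = {r.category: r for r in enrichment_or(called, labels.index,
                                                    labels)}
        r = res["X"]
        assert (r.a, r.b, r.c, r.d) == (20, 80, 30, 170)
        assert r.odds_ratio == pytest.approx((20 * 170) / (80 * 30))

    def test_zero_cell_haldane_anscombe(self):
        labels = labelled_probes(["X"] * 50 + ["Y"] * 50)
        called = labels.index[50:]  # a=0, b=100 impossible; use 50
        res = {r.category: r for r in enrichment_or(called, labels.index,
                                                    labels)}
        r = res["X"]
        assert (r.a, r.b, r.c, r.d) == (0, 50, 50, 50)
        expected = (0.5 * 50.5) / (50.5 * 50.5)
        assert r.odds_ratio == pytest.approx(expected)

    def test_category_a_counts_sum_to_called(self):
        rng = np.random.default_rng(0)
        labels = labelled_probes(rng.choice(list("ABCD"), size=500))
        called = labels.index[rng.random(500) < 0.3]
        res = enrichment_or(called, labels.index, labels)
        assert sum(r.a for r in res) == len(called)
        assert all(r.a + r.b == len(called) for r in res)
        assert all(r.c + r.d == 500 for r in res)

    def test_two_category_reciprocal(self):
        rng = np.random.default_rng(1)
        labels = labelled_probes(rng.choice(["X", "Y"], size=400))
        called = labels.index[rng.random(400) < 0.25]
        res = {r.category: r for r in enrichment_or(called, labels.index,
                                                    labels)}
        assert res["X"].odds_ratio == pytest.approx(1 / res["Y"].odds_ratio)

    def test_called_outside_background_rejected(self):
        labels = labelled_probes(["X", "Y"])
        with pytest.raises(ValidationError, match="subset"):
            enrichment_or(pd.Index(["zz"]), labels.index, labels)

    def test_chi2_matches_permutation_chi2(self):
        # Pearson chi-squared p vs a margin-preserving permutation null
        # (mid-p for the discrete ties), moderate counts
        rng = np.random.default_rng(7)
        from test_acceptance import permutation_chi2_midp
        from fetalmeth.enrichment import chi2_p_2x2
        for _ in range(8):
            a, b = int(rng.integers(20, 120)), int(rng.integers(20, 120))
            c, d = int(rng.integers(40, 200)), int(rng.integers(40, 200))
            p_perm = permutation_chi2_midp(a, b, c, d, rng, n_sim=6_000)
            assert p_perm == pytest.approx(chi2_p_2x2(a, b, c, d), abs=0.05)


class TestChromatinStates:
    def test_single_state_gives_or_one(self):
        manifest = pd.DataFrame({"probe_id": [f"p{i}" for i in range(10)],
                                 "chrom": "chr1",
                                 "pos": np.arange(10) * 100 + 50})
        seg = IntervalTrack("seg", pd.DataFrame(
            [("chr1", 0, 10_000, "Enhancer")],
            columns=["chrom", "start", "end", "label"]))
        called = pd.Index([f"p{i}" for i in range(3)])
        res = chromatin_state_enrichment(called, pd.Index(manifest["probe_id"]),
                                         manifest, seg)
        assert len(res) == 1 and res[0].odds_ratio == pytest.approx(1.0)

    def test_counts_match_brute_force_membership(self, rng):
        starts = np.sort(rng.choice(100_000, size=40, replace=False))
        rows = []
        for i, s in enumerate(starts[:-1]):
            rows.append(("chr1", int(s), int(starts[i + 1]),
                         str(rng.choice(["A", "B", "C"]))))
        seg = IntervalTrack("seg", pd.DataFrame(
            rows, columns=["chrom", "start", "end", "label"]))
        positions = np.sort(rng.choice(120_000, size=1_000, replace=False)) + 1
        manifest = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(len(positions))],
            "chrom": "chr1", "pos": positions})
        got = probe_state_labels(manifest, seg)
        tree = IntervalTree()
        for r in rows:
            tree.addi(r[1], r[2], r[3])
        for pid, pos in zip(manifest["probe_id"], manifest["pos"]):
            hits = tree.overlap(pos - 1, pos)  # half-open base pos-1
            expected = sorted(h.data for h in hits)[0] if hits else "unsegmented"
            assert got[pid] == expected

    def test_planted_enhancers_rank_first(self, small_data):
        from fetalmeth.calling import call_dynamic
        gom, lom = call_dynamic(small_data.beta, small_data.meta, "muscle")
        res = chromatin_state_enrichment(
            lom.probes, pd.Index(small_data.manifest["probe_id"]),
            small_data.manifest, small_data.states)
        best = max(res, key=lambda r: r.odds_ratio)
        assert best.category == "Enhancer" and best.odds_ratio > 1


def make_genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                       "tx_start", "tx_end"])


class TestNearestGene:
    def test_nearer_endpoint_wins(self):
        genes = make_genes([("gA", "chr1", "+", 6_000, 9_000),
                            ("gB", "chr1", "+", 1_000, 3_000)])
        items = pd.DataFrame({"item_id": ["x"], "chrom": ["chr1"],
                              "pos": [5_000]})
        got = nearest_gene(items, genes)
        assert got.loc[0, "gene_id"] == "gA"
        assert got.loc[0, "distance"] == -1_000  # upstream (left) of gA span

    def test_probe_at_tss_distance_zero(self):
        genes = make_genes([("gA", "chr1", "+", 6_000, 9_000)])
        items = pd.DataFrame({"item_id": ["x"], "chrom": ["chr1"],
                              "pos": [6_000]})
        got = nearest_gene(items, genes)
        assert got.loc[0, "gene_id"] == "gA" and got.loc[0, "distance"] == 0

    def test_brute_force_agreement(self, rng):
        genes = make_genes([
            (f"g{i}", "chr1", rng.choice(["+", "-"]), int(s),
             int(s + rng.integers(1_000, 20_000)))
            for i, s in enumerate(np.sort(rng.choice(500_000, 20)) + 10_000)])
        items = pd.DataFrame({
            "item_id": [f"x{i}" for i in range(100)], "chrom": "chr1",
            "pos": np.sort(rng.choice(600_000, 100, replace=False)) + 1})
        got = nearest_gene(items, genes).set_index("item_id")
        for item in items.itertuples(index=False):
            best = None
            for g in genes.itertuples(index=False):
                tss = g.tx_start if g.strand == "+" else g.tx_end
                tes = g.tx_end if g.strand == "+" else g.tx_start
                inside = g.tx_start <= item.pos <= g.tx_end
                d = 0 if inside else min(abs(item.pos - tss),
                                         abs(item.pos - tes))
                key = (d, abs(item.pos - tss), g.gene_id)
                if best is None or key < best:
                    best = key
            assert got.loc[item.item_id, "gene_id"] == best[2]

    def test_translation_invariance(self, rng):
        genes = make_genes([("g1", "chr1", "+", 50_000, 70_000),
                            ("g2", "chr1", "-", 90_000, 95_000)])
        items = pd.DataFrame({"item_id": [f"x{i}" for i in range(50)],
                              "chrom": "chr1",
                              "pos": rng.integers(1, 120_000, size=50)})
        base = nearest_gene(items, genes)
        shift = 7_777_777
        moved = nearest_gene(items.assign(pos=items["pos"] + shift),
                             genes.assign(tx_start=genes["tx_start"] + shift,
                                          tx_end=genes["tx_end"] + shift))
        assert (base["gene_id"] == moved["gene_id"]).all()
        assert (base["distance"] == moved["distance"]).all()

    def test_region_midpoint_items(self):
        r = Region("chr1", 100, 300, ["p1"], 3, 0)
        items = regions_to_items([r])
        assert items.loc[0, "pos"] == 200


class TestMetaprofile:
    def region(self):
        return Region("chr1", 20_001, 30_000, [], 3, 0)

    def test_zero_signal_everywhere(self):
        sig = IntervalTrack("sig")
        prof = region_metaprofile(sig, [self.region()], n_bins=10)
        assert prof.shape == (30,) and (prof == 0).all()

    def test_single_tag_at_midpoint_hits_central_bin(self):
        sig = IntervalTrack("sig", pd.DataFrame(
            [("chr1", 24_999, 25_001, "")],
            columns=["chrom", "start", "end", "label"]))
        prof = region_metaprofile(sig, [self.region()], n_bins=10)
        assert prof.sum() == 1.0
        hot = int(np.flatnonzero(prof)[0])
        assert 10 <= hot < 20  # middle (body) third
        assert hot in (14, 15)

    def test_uniform_tags_give_flat_profile(self, rng):
        # one tag every 50 bp -> lambda = 0.02 per bp
        positions = np.arange(10_000, 40_001, 50)
        sig = IntervalTrack("sig", pd.DataFrame(
            {"chrom": "chr1", "start": positions - 1, "end": positions + 1,
             "label": ""}))
        prof = region_metaprofile(sig, [self.region()], flank=5_000, n_bins=10)
        # flank bins: 500 bp wide -> 10 tags; body bins 1,000 bp -> 20 tags
        assert prof[:10] == pytest.approx(np.full(10, 10.0), abs=2)
        assert prof[10:20] == pytest.approx(np.full(10, 20.0), abs=2)
        assert prof[20:] == pytest.approx(np.full(10, 10.0), abs=2)
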