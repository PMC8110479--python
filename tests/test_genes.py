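"""Gene blocks, orientation statistics, junction sites and genomic tracks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinochrom import genes as gn
from dinochrom import genome_io as gio


def gene_table(strands, chrom="chr1", start=1000, glen=500, gap=500):
    rows = []
    x = start
    for i, s in enumerate(strands):
        rows.append((f"g{i:03d}", chrom, x, x + glen, s))
        x += glen + gap
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )


class TestFindBlocks:
    def test_run_length_encoding(self):
        blocks = gn.find_blocks(gene_table("++---"))
        assert blocks["size"].tolist() == [2, 3]
        assert blocks["strand"].tolist() == ["+", "-"]

    def test_all_cooriented_single_block_per_chromosome(self):
        g = pd.concat(
            [gene_table("++++", chrom="chr1"), gene_table("+++", chrom="chr2")]
        )
        blocks = gn.find_blocks(g)
        assert len(blocks) == 2
        assert blocks["size"].tolist() == [4, 3]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from("+-"), min_size=1, max_size=60))
    def test_blocks_partition_genes_and_alternate(self, strands):
        blocks = gn.find_blocks(gene_table(strands))
        assert blocks["size"].sum() == len(strands)
        s = blocks["strand"].tolist()
        assert all(a != b for a, b in zip(s, s[1:]))

    def test_cumulative_fraction(self):
        blocks = gn.find_blocks(gene_table("++---+----"))  # sizes 2,3,1,4
        cum = gn.cumulative_gene_fraction(blocks)
        got = dict(zip(cum["min_size"], cum["gene_fraction"]))
        assert got[1] == 1.0
        assert got[2] == pytest.approx(9 / 10)
        assert got[3] == pytest.approx(7 / 10)
        assert got[4] == pytest.approx(4 / 10)


class TestOrientationChanges:
    def test_cooriented_window_has_zero_changes(self):
        r = gn.orientation_change_stats(gene_table("+" * 10), window=10)
        assert r["observed"][0] == 1.0

    def test_alternating_window_has_max_changes(self):
        r = gn.orientation_change_stats(gene_table("+-" * 5), window=10)
        assert r["observed"][9] == 1.0

    def test_null_is_exact_binomial_by_enumeration(self):
        for window in (3, 5, 6):
            r = gn.orientation_change_stats(gene_table("+" * window), window)
            counts = np.zeros(window)
            for seq in itertools.product("+-", repeat=window):
                ch = sum(a != b for a, b in zip(seq, seq[1:]))
                counts[ch] += 1
            np.testing.assert_allclose(r["null"], counts / counts.sum())

    def test_null_mean_for_window_ten(self):
        r = gn.orientation_change_stats(gene_table("+" * 10), window=10)
        assert float((r["null"] * np.arange(10)).sum()) == pytest.approx(4.5)

    def test_short_chromosomes_skipped(self):
        g = pd.concat(
            [gene_table("+-", chrom="chrS"), gene_table("+" * 12, chrom="chrL")]
        )
        r = gn.orientation_change_stats(g, window=10)
        assert r["n_windows"] == 3  # only chrL contributes 12-10+1 windows


class TestCallSites:
    def test_convergent_site_at_gap_midpoint(self):
        g = gene_table("++--", glen=400, gap=100)
        # inter-block gap between gene 1 end and gene 2 start
        blocks = gn.find_blocks(g)
        sites = gn.call_sites(blocks)
        assert len(sites) == 1
        left_end = g.loc[1, "end"]
        right_start = g.loc[2, "start"]
        assert sites.loc[0, "kind"] == "convergent"
        assert sites.loc[0, "position"] == (left_end + right_start) // 2
        assert sites.loc[0, "orientation"] == "+"
        assert not sites.loc[0, "overlap"]

    def test_divergent_site_kind(self):
        sites = gn.call_sites(gn.find_blocks(gene_table("--++")))
        assert sites.loc[0, "kind"] == "divergent"
        assert sites.loc[0, "orientation"] == "-"

    def test_single_block_gives_no_sites(self):
        sites = gn.call_sites(gn.find_blocks(gene_table("+++")))
        assert len(sites) == 0

    def test_overlapping_blocks_flagged(self):
        g = gene_table("++--")
        g.loc[2, "start"] = g.loc[1, "end"] - 300  # right block starts inside left
        g.loc[2, "end"] = g.loc[2, "start"] + 400
        sites = gn.call_sites(gn.find_blocks(g))
        assert sites.loc[0, "overlap"]

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from("+-"), min_size=2, max_size=40))
    def test_site_count_identity_without_filtering(self, strands):
        blocks = gn.find_blocks(gene_table(strands))
        sites = gn.call_sites(blocks)
        assert len(sites) == len(blocks) - 1

    def test_expression_filter_merges_across_silent_blocks(self, desk_genes):
        blocks = gn.find_blocks(desk_genes.genes)
        sites = gn.call_sites(
            blocks, expression=(desk_genes.plus, desk_genes.minus), min_expr=0.5
        )
        truth = desk_genes.truth
        n_conv = sum(len(v) for v in truth.boundaries.values())
        n_div = sum(len(v) for v in truth.divergent.values())
        counts = sites["kind"].value_counts()
        assert counts.get("convergent", 0) == n_conv
        assert counts.get("divergent", 0) == n_div


class TestGcTrack:
    def asm(self, seq):
        return gio.GenomeAssembly(
            chromosomes=[("chr1", len(seq))], sequence={"chr1": seq}
        )

    def test_pure_gc_window(self):
        t = gn.gc_track(self.asm("GCGC"), window=4)
        assert t["value"].iloc[0] == 1.0

    def test_pure_at_window(self):
        t = gn.gc_track(self.asm("ATAT"), window=4)
        assert t["value"].iloc[0] == 0.0

    def test_majority_n_window_undefined(self):
        t = gn.gc_track(self.asm("N" * 7 + "GCA"), window=10)
        assert np.isnan(t["value"].iloc[0])

    def test_ns_excluded_from_denominator(self):
        t = gn.gc_track(self.asm("GGNNAT" + "AT"), window=8)
        assert t["value"].iloc[0] == pytest.approx(2 / 6)


def constant_track(value, n=100, width=1000, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "value": value,
        }
    )


class TestFeatureProfile:
    LENGTHS = {"chr1": 100_000}

    def test_constant_track_gives_flat_profile(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "position": [50_000]})
        prof = gn.feature_profile(
            constant_track(3.5), sites, self.LENGTHS, flank=10_000,
            window=1000, step=1000,
        )
        np.testing.assert_allclose(prof["mean"], 3.5)

    def test_single_site_profile_equals_raw_windows(self):
        rng = np.random.default_rng(5)
        t = constant_track(0.0)
        t["value"] = rng.random(len(t))
        sites = pd.DataFrame({"chrom": ["chr1"], "position": [50_000]})
        prof = gn.feature_profile(
            t, sites, self.LENGTHS, flank=5_000, window=1000, step=1000
        )
        for off, m in zip(prof["offset"], prof["mean"]):
            idx = (50_000 + off) // 1000
            assert m == pytest.approx(t["value"].iloc[idx])

    def test_out_of_range_sites_dropped_and_counted(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "position": [500, 50_000]}
        )
        prof = gn.feature_profile(
            constant_track(1.0), sites, self.LENGTHS, flank=10_000,
            window=1000, step=1000,
        )
        assert prof.attrs["n_dropped"] == 1

    def test_mirror_equivariance(self):
        """A minus-oriented site on the mirrored track reproduces the
        profile of a plus-oriented site on the original."""
        rng = np.random.default_rng(6)
        vals = rng.random(100)
        t_fwd = constant_track(0.0)
        t_fwd["value"] = vals
        t_rev = constant_track(0.0)
        t_rev["value"] = vals[::-1]
        pos = 40_000
        mirrored_pos = 100_000 - pos
        fwd_sites = pd.DataFrame(
            {"chrom": ["chr1"], "position": [pos], "orientation": ["+"]}
        )
        rev_sites = pd.DataFrame(
            {"chrom": ["chr1"], "position": [mirrored_pos], "orientation": ["-"]}
        )
        p1 = gn.feature_profile(
            t_fwd, fwd_sites, self.LENGTHS, flank=8_000, window=1000, step=1000
        )
        p2 = gn.feature_profile(
            t_rev, rev_sites, self.LENGTHS, flank=8_000, window=1000, step=1000
        )
        np.testing.assert_allclose(p1["mean"], p2["mean"])

    def test_stranded_convergent_profile_separates_strands(self, desk_genes):
        blocks = gn.find_blocks(desk_genes.genes)
        sites = gn.call_sites(
            blocks, expression=(desk_genes.plus, desk_genes.minus), min_expr=0.5
        )
        conv = sites[sites["kind"] == "convergent"]
        prof = gn.feature_profile_stranded(
            desk_genes.plus,
            desk_genes.minus,
            conv,
            desk_genes.assembly.lengths,
            flank=30_000,
            window=1000,
            step=1000,
        )
        up = prof[prof["offset"] < -10_000]
        dn = prof[prof["offset"] >= 10_000]
        assert up["top"].sum() / (up["top"].sum() + up["bottom"].sum()) >= 0.9
        assert dn["bottom"].sum() / (dn["top"].sum() + dn["bottom"].sum()) >= 0.9


class TestTelomereProfile:
    def test_constant_track_flat(self):
        lengths = {"chr1": 100_000}
        prof = gn.telomere_profile(
            constant_track(2.0), lengths, span=20_000, min_chrom=50_000
        )
        np.testing.assert_allclose(prof["mean"], 2.0)

    def test_short_chromosome_excluded(self):
        lengths = {"chr1": 4_000_000}
        with pytest.raises(ValueError, match="min_chrom"):
            gn.telomere_profile(
                constant_track(1.0, n=4000), lengths,
                span=2_500_000, min_chrom=5_000_000,
            )

    def test_linear_gradient_slope_recovered(self):
        n, width = 8000, 1000
        lengths = {"chr1": n * width}
        x = (np.arange(n) + 0.5) * width
        L = n * width
        dist = np.minimum(x, L - x)
        slope = -2e-8
        t = constant_track(0.0, n=n, width=width)
        t["value"] = 0.5 + slope * dist
        prof = gn.telomere_profile(t, lengths, span=2_000_000, min_chrom=5_000_000)
        fit = np.polyfit(prof["distance_to_end"], prof["mean"], 1)
        assert fit[0] == pytest.approx(slope, rel=0.05)


class TestTrackCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(7)
        a = constant_track(0.0)
        a["value"] = rng.random(100)
        b = a.copy()
        b["value"] = -a["value"]
        corr, n = gn.track_correlations({"a": a, "same": a.copy(), "neg": b})
        assert corr.loc["a", "same"] == pytest.approx(1.0)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)
        assert n == 100

    def test_planted_correlation_recovered(self):
        from dinochrom import simulate as sim

        ta, tb = sim.correlated_tracks(1000, rho=0.6, seed=11)
        corr, n = gn.track_correlations({"a": ta, "b": tb})
        assert n >= 500
        assert corr.loc["a", "b"] == pytest.approx(0.6, abs=0.05)

    def test_too_few_common_bins_rejected(self):
        a = constant_track(1.0, n=2)
        with pytest.raises(ValueError):
            gn.track_correlations({"a": a, "b": a.copy()})
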