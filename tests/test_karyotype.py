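"""Clustering, misjoin splitting, ordering/orienting, copy number."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import kendalltau

from dinochrom import genome_io as gio
from dinochrom import karyotype as kar
from dinochrom import simulate as sim


def toy_matrix(block_sizes, intra=5.0, inter=0.0, res=50_000, noise_seed=None):
    """Block-structured balanced matrix; one scaffold per block row span."""
    n = sum(block_sizes)
    A = np.full((n, n), inter)
    off = 0
    for b in block_sizes:
        A[off : off + b, off : off + b] = intra
        off += b
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        A = A + rng.random((n, n)) * 1e-3
        A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    chroms = [(f"scf{i}", b * res) for i, b in enumerate(block_sizes)]
    asm = gio.GenomeAssembly(chromosomes=chroms)
    bt = gio.bin_genome(asm, res)
    m = gio.ContactMatrix(
        bin_table=bt, counts=sp.csr_matrix(A), weights=np.ones(n), balanced=True
    )
    return m, kar.scaffold_set_from_bins(bt)


class TestKaryotypeCluster:
    def test_block_diagonal_recovers_two_clusters(self):
        # 4 scaffolds, two chromosomes, zero trans between chromosomes
        m, ss = toy_matrix([4, 4, 4, 4])
        A = np.asarray(m.counts.todense())
        A[:8, 8:] = 0.0
        A[8:, :8] = 0.0
        A[:8, :8] = 5.0
        A[8:, 8:] = 5.0
        np.fill_diagonal(A, 0)
        m.counts = sp.csr_matrix(A)
        res = kar.karyotype_cluster(m, ss)
        assert res.k == 2
        assert res.ambiguous == []
        labs = [res.assignment[f"scf{i}"] for i in range(4)]
        assert labs[0] == labs[1] != labs[2] == labs[3]

    def test_equal_affinity_scaffold_is_ambiguous(self):
        # scf2 contacts both chromosomes equally
        m, ss = toy_matrix([4, 4, 4])
        A = np.zeros((12, 12))
        A[:4, :4] = 5.0
        A[4:8, 4:8] = 5.0
        A[8:, :4] = 2.0
        A[:4, 8:] = 2.0
        A[8:, 4:8] = 2.0
        A[4:8, 8:] = 2.0
        np.fill_diagonal(A, 0)
        m.counts = sp.csr_matrix(A)
        res = kar.karyotype_cluster(m, ss, k=2, ambiguity_ratio=0.5)
        assert "scf2" in res.ambiguous

    def test_fewer_scaffolds_than_k_rejected(self):
        m, ss = toy_matrix([4, 4])
        with pytest.raises(ValueError):
            kar.karyotype_cluster(m, ss, k=5)

    def test_below_min_length_reported_separately(self):
        m, ss = toy_matrix([4, 4])
        ss.scaffolds.loc[len(ss.scaffolds)] = ("tiny", 10_000)
        bt = ss.bin_table
        assert ss.below_min == ["tiny"]

    def test_partition_property(self):
        m, ss = toy_matrix([4, 4, 4, 4], noise_seed=1)
        res = kar.karyotype_cluster(m, ss, k=2)
        names = set(ss.usable["name"])
        assigned = set(res.assignment)
        amb = set(res.ambiguous)
        assert assigned | amb == names
        assert assigned & amb == set()


class TestSplitMisjoins:
    def test_homogeneous_scaffold_returned_intact(self, desk):
        # reuse the desk matrix: every desk chromosome is its own scaffold
        bt = desk.matrix.bin_table
        ss = kar.scaffold_set_from_bins(bt)
        res = kar.karyotype_cluster(desk.matrix, ss, k=len(bt.chrom_lengths))
        sub = kar.split_misjoins(desk.matrix, ss, res)
        assert len(sub) == len(bt.chrom_lengths)
        assert (sub["start"] == 0).all()


class TestOrderOrient:
    def test_single_member_is_trivial(self):
        m, ss = toy_matrix([4])
        cs = kar.order_orient(m, ["scf0"], ss)
        assert cs.members == [("scf0", "+", 0.0)]

    def test_symmetric_tie_breaks_lexicographically(self):
        m, ss = toy_matrix([4, 4], intra=0.0, inter=1.0)
        A = np.ones((8, 8))
        np.fill_diagonal(A, 0)
        m.counts = sp.csr_matrix(A)
        cs = kar.order_orient(m, ["scf1", "scf0"], ss)
        assert cs.order == ["scf0", "scf1"]
        assert all(conf == 0.0 for _, _, conf in cs.members)

    def test_input_order_invariance(self):
        spec = sim.SyntheticSpec(
            seed=31, n_chromosomes=1, chrom_lengths=(8_000_000,),
            n_pairs=300_000, trans_fraction=0.0,
        )
        asm, _, _, truth = sim.generate_genome(spec, sequence=False)
        pairs = sim.generate_contacts(asm, truth, spec)
        scf_asm, ft = sim.fragment_assembly(asm, truth, 1_500_000, 0.0)
        spairs = sim.map_pairs_to_scaffolds(pairs, ft)
        bt = gio.bin_genome(scf_asm, 40_000)
        m, _ = gio.pairs_to_matrix(spairs, bt)
        m = gio.ice_balance(m)
        ss = kar.scaffold_set_from_bins(bt)
        members = list(ft.fragments)
        a = kar.order_orient(m, members, ss)
        b = kar.order_orient(m, members[::-1], ss)
        assert a.members == b.members

    def test_five_subscaffolds_order_and_orientation_recovered(self):
        spec = sim.SyntheticSpec(
            seed=33, n_chromosomes=1, chrom_lengths=(10_000_000,),
            n_pairs=1_000_000, trans_fraction=0.0,
        )
        asm, _, _, truth = sim.generate_genome(spec, sequence=False)
        pairs = sim.generate_contacts(asm, truth, spec)
        scf_asm, ft = sim.fragment_assembly(
            asm, truth, 2_000_000, 0.0, flip_prob=0.5
        )
        spairs = sim.map_pairs_to_scaffolds(pairs, ft)
        bt = gio.bin_genome(scf_asm, 40_000)
        m, _ = gio.pairs_to_matrix(spairs, bt)
        m = gio.ice_balance(m)
        ss = kar.scaffold_set_from_bins(bt)
        cs = kar.order_orient(m, list(ft.fragments), ss)
        truth_start = {s: ft.fragments[s][0][1] for s in ft.fragments}
        truth_orient = {s: ft.fragments[s][0][3] for s in ft.fragments}
        got = [truth_start[n] for n in cs.order]
        tau = kendalltau(got, sorted(got)).statistic
        assert abs(tau) == pytest.approx(1.0)
        # orientation scored in the frame of the recovered direction
        flipped = tau < 0
        for name, orient, conf in cs.members:
            want = truth_orient[name]
            if flipped:
                want = "+" if want == "-" else "-"
            assert orient == want


class TestAssignHighCopy:
    def test_cluster_assigned_to_strongest_chromosome(self):
        m, ss = toy_matrix([4, 4, 2])
        A = np.zeros((10, 10))
        A[:4, :4] = 5.0
        A[4:8, 4:8] = 5.0
        A[8:, :4] = 3.0  # repeats contact chromosome 0 strongly
        A[:4, 8:] = 3.0
        A[8:, 4:8] = 0.3
        A[4:8, 8:] = 0.3
        np.fill_diagonal(A, 0)
        m.counts = sp.csr_matrix(A)
        res = kar.KaryotypeResult(
            assignment={"scf0": 0, "scf1": 1},
            ambiguous=["scf2"],
            below_min=[],
            merge_heights=np.array([]),
            k=2,
        )
        table = kar.assign_high_copy(m, {"rep": ["scf2"]}, ss, res)
        assert table.loc[0, "chromosome"] == 0
        assert table.loc[0, "margin"] == pytest.approx(10.0)

    def test_planted_repeat_family_assigned_home(self):
        fam = sim.RepeatFamily("repA", length=200_000, copies=4, home_chrom=2)
        spec = sim.SyntheticSpec(
            seed=41, n_chromosomes=4, chrom_length=4_000_000,
            repeat_families=(fam,), n_pairs=400_000,
        )
        asm, _, _, truth = sim.generate_genome(spec, sequence=False)
        pairs = sim.generate_contacts(asm, truth, spec)
        bt = gio.bin_genome(asm, 40_000)
        m, _ = gio.pairs_to_matrix(pairs, bt)
        m = gio.ice_balance(m)
        ss = kar.scaffold_set_from_bins(bt)
        # cluster only the true chromosomes; the family is the set-aside part
        chrom_names = [c for c, _ in asm.chromosomes if c != "repA"]
        res = kar.karyotype_cluster(m, ss, k=None)
        res.assignment.pop("repA", None)
        table = kar.assign_high_copy(m, {"famA": ["repA"]}, ss, res)
        home_cluster = res.assignment["chr3"]
        assert table.loc[0, "chromosome"] == home_cluster
        assert table.loc[0, "margin"] > 2


class TestCopyNumber:
    def bins(self, lengths, res=40_000):
        asm = gio.GenomeAssembly(
            chromosomes=[(n, L) for n, L in lengths.items()]
        )
        return gio.bin_genome(asm, res)

    def coverage(self, bt, values):
        t = bt.bins.copy()
        t["value"] = values
        return t

    def test_constructed_elevenfold_ratio(self):
        bt = self.bins({"chrA": 400_000, "rep": 200_000})
        vals = np.array([10.0] * 10 + [110.0] * 5)
        est = kar.copy_number(
            self.coverage(bt, vals), bt, ["chrA"], {"c1": ["rep"]}
        )
        assert est.set_index("cluster").at["c1", "copy_number"] == pytest.approx(
            11.0
        )

    def test_equal_coverage_gives_unity(self):
        bt = self.bins({"chrA": 400_000, "rep": 200_000})
        vals = np.full(15, 25.0)
        est = kar.copy_number(
            self.coverage(bt, vals), bt, ["chrA"], {"c1": ["rep"]}
        )
        assert est.set_index("cluster").at["c1", "copy_number"] == 1.0

    def test_invariant_under_global_rescaling(self):
        bt = self.bins({"chrA": 400_000, "rep": 200_000})
        rng = np.random.default_rng(8)
        vals = rng.poisson(20, 15).astype(float) + 1
        a = kar.copy_number(self.coverage(bt, vals), bt, ["chrA"], {"c": ["rep"]})
        b = kar.copy_number(
            self.coverage(bt, 13.0 * vals), bt, ["chrA"], {"c": ["rep"]}
        )
        pd.testing.assert_frame_equal(a, b)

    def test_zero_reference_rejected(self):
        bt = self.bins({"chrA": 400_000, "rep": 200_000})
        vals = np.zeros(15)
        with pytest.raises(ValueError, match="reference"):
            kar.copy_number(self.coverage(bt, vals), bt, ["chrA"], {"c": ["rep"]})

    def test_planted_four_copy_family_estimated(self):
        fam = sim.RepeatFamily("repA", length=200_000, copies=4, home_chrom=0)
        spec = sim.SyntheticSpec(
            seed=42, n_chromosomes=2, chrom_length=2_000_000,
            repeat_families=(fam,), coverage_depth=250.0,
        )
        asm, _, _, truth = sim.generate_genome(spec, sequence=False)
        bt = gio.bin_genome(asm, 10_000)
        cov = sim.generate_coverage(bt, truth, spec)
        est = kar.copy_number(cov, bt, ["chr1", "chr2"], {"famA": ["repA"]})
        assert est.set_index("cluster").at["famA", "copy_number"] == pytest.approx(
            4.0, abs=0.2
        )
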