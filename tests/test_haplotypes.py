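"""Region haplotypes: MAF filter, recombinant screening, haplogroup clustering,
frequency tables and the pairwise-difference MST network."""

import numpy as np
import pytest

import ovintro as ov
from ovintro.haplotypes import RegionHaplotypes
from ovintro.panel import Window

from conftest import tiny_panel
from oracles import mst_weight_oracle


def region_from_matrix(mat, breeds=None):
    """RegionHaplotypes straight from a (haps x sites) 0/1 matrix."""
    mat = np.asarray(mat, dtype=np.int8)
    n = mat.shape[0]
    ids = [f"s{i // 2}_h{i % 2}" for i in range(n)]
    breeds = breeds or {h: "b" for h in ids}
    return RegionHaplotypes(
        Window("c", 0, 1000), np.arange(mat.shape[1]) * 10 + 10, mat, ids, breeds
    )


def popmap_for_ids(ids, breed="b"):
    samples = sorted({h.rpartition("_h")[0] for h in ids})
    return ov.PopMap({s: breed for s in samples}, {breed: breed})


class TestExtractRegion:
    def make(self, freqs, n_haps=20, seed=0):
        rng = np.random.default_rng(seed)
        mat = (rng.random((len(freqs), n_haps)) < np.asarray(freqs)[:, None]).astype(np.int8)
        panel = tiny_panel(mat, samples=[f"s{i}" for i in range(n_haps // 2)])
        pm = ov.PopMap({f"s{i}": "b" for i in range(n_haps // 2)}, {"b": "b"})
        return panel, pm

    def test_exact_maf_boundary_removed(self):
        # 20 haplotypes: exactly 1 alt allele = MAF 0.05 -> removed (<= rule)
        mat = np.zeros((3, 20), dtype=np.int8)
        mat[0, 0] = 1              # MAF 0.05: removed
        mat[1, :2] = 1             # MAF 0.10: kept
        mat[2, :10] = 1            # MAF 0.50: kept
        panel = tiny_panel(mat, samples=[f"s{i}" for i in range(10)])
        pm = ov.PopMap({f"s{i}": "b" for i in range(10)}, {"b": "b"})
        rh = ov.extract_region(panel, pm, Window("chr1", 0, 1000))
        assert rh.n_sites == 2

    def test_monomorphic_region_errors(self):
        panel, pm = self.make([0.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="MAF"):
            ov.extract_region(panel, pm, Window("chr1", 0, 1000))

    def test_retained_count_equals_brute_force(self):
        rng = np.random.default_rng(3)
        freqs = rng.random(60)
        panel, pm = self.make(freqs, n_haps=40, seed=3)
        rh = ov.extract_region(panel, pm, Window("chr1", 0, 10_000))
        mat = panel.alleles["chr1"]
        expected = sum(
            1 for i in range(60)
            if min(mat[i].mean(), 1 - mat[i].mean()) > 0.05
        )
        assert rh.n_sites == expected

    def test_filter_commutes_with_extraction(self):
        rng = np.random.default_rng(5)
        freqs = rng.random(80)
        panel, pm = self.make(freqs, n_haps=40, seed=5)
        whole = ov.extract_region(panel, pm, Window("chr1", 0, 100_000))
        # extracting a subwindow then filtering == filtering then subsetting
        sub = ov.extract_region(panel, pm, Window("chr1", 0, 4_010))
        keep = whole.positions < 4_010
        assert np.array_equal(sub.positions, whole.positions[keep])
        assert np.array_equal(sub.matrix, whole.matrix[:, keep])


class TestScreenRecombinants:
    def build(self, n_sites=40, n_each=10, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, n_sites).astype(np.int8)
        b = 1 - a
        c = a.copy()
        c[::2] = 1 - c[::2]
        rows = [a] * n_each + [b] * n_each + [c] * n_each
        return a, b, c, rows

    def test_consensus_member_kept_chimera_flagged(self):
        a, b, c, rows = self.build()
        chimera = np.r_[a[:20], b[20:]]
        rows = rows + [chimera]
        rh = region_from_matrix(np.array(rows))
        kept, flagged = ov.screen_recombinants(rh)
        assert rh.hap_ids[-1] in flagged
        assert rh.hap_ids[0] in kept
        assert len(flagged) == 1

    def test_simulated_crossovers_recall(self):
        a, b, c, rows = self.build(n_sites=60, n_each=8, seed=2)
        rng = np.random.default_rng(2)
        majors = [a, b, c]
        n_chim = 20
        for _ in range(n_chim):
            i, j = rng.choice(3, size=2, replace=False)
            k = int(rng.integers(15, 45))
            rows.append(np.r_[majors[i][:k], majors[j][k:]])
        rh = region_from_matrix(np.array(rows))
        kept, flagged = ov.screen_recombinants(rh)
        chim_ids = rh.hap_ids[-n_chim:]
        recall = sum(1 for h in chim_ids if h in flagged) / n_chim
        assert recall >= 0.9

    def test_too_few_distinct_haplotypes_warns(self):
        rh = region_from_matrix(np.array([[0, 1, 0]] * 4 + [[1, 0, 1]] * 4))
        with pytest.warns(UserWarning, match="distinct"):
            kept, flagged = ov.screen_recombinants(rh, k_major=3)
        assert len(kept) == 8


class TestClusterHaplogroups:
    def test_three_planted_clusters(self):
        rng = np.random.default_rng(4)
        n_sites = 100
        centers = [rng.integers(0, 2, n_sites).astype(np.int8) for _ in range(3)]
        # well separated: pairwise distance ~50; members within 2 of center
        rows, labels = [], []
        for ci, center in enumerate(centers):
            for _ in range(10 - 2 * ci):  # sizes 10, 8, 6
                h = center.copy()
                flip = rng.choice(n_sites, size=2, replace=False)
                h[flip] = 1 - h[flip]
                rows.append(h)
                labels.append(ci)
        rh = region_from_matrix(np.array(rows))
        groups = ov.cluster_haplogroups(rh, max_diff_frac=0.05)
        assert len(groups) == 3
        assert [g.size for g in groups] == [10, 8, 6]
        member_sets = [set(g.members) for g in groups]
        for ci in range(3):
            ids = {rh.hap_ids[i] for i, l in enumerate(labels) if l == ci}
            assert ids in member_sets

    def test_all_identical_single_group(self):
        rh = region_from_matrix(np.tile([0, 1, 1, 0], (6, 1)))
        groups = ov.cluster_haplogroups(rh)
        assert len(groups) == 1 and groups[0].size == 6

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 2, (12, 30)).astype(np.int8)
        rh = region_from_matrix(rows)
        g1 = ov.cluster_haplogroups(rh, max_diff_frac=0.3)
        order = list(rng.permutation(rh.hap_ids))
        g2 = ov.cluster_haplogroups(rh, max_diff_frac=0.3, hap_ids=order)
        assert [sorted(g.members) for g in g1] == [sorted(g.members) for g in g2]


class TestHaplogroupFrequencies:
    def build_counts(self, spec):
        """spec: list of (breed, n_carriers, n_total) for one haplogroup."""
        sb, members, others = {}, [], []
        for breed, carriers, total in spec:
            assert total % 2 == 0 and carriers <= total
            for i in range(total // 2):
                s = f"{breed}_{i:04d}"
                sb[s] = breed
            haps = [f"{breed}_{i:04d}_h{k}" for i in range(total // 2) for k in (0, 1)]
            members += haps[:carriers]
            others += haps[carriers:]
        pm = ov.PopMap(sb, {b: b for b, _, _ in spec})
        g1 = ov.Haplogroup("hap-1", sorted(members), np.zeros(1, dtype=np.int8))
        g2 = ov.Haplogroup("hap-2", sorted(others), np.zeros(1, dtype=np.int8))
        return [g1, g2], pm

    def test_printed_overall_frequency(self):
        # 155 carriers among 1831 grouped haplotypes -> 0.085; the odd total
        # arises when one haplotype of one sample falls in no haplogroup
        groups, pm = self.build_counts([("all", 155, 1832)])
        groups[1].members.pop()  # leave one haplotype unassigned
        tab = ov.haplogroup_frequencies(groups, pm)
        row = tab[(tab.haplogroup == "hap-1") & (tab.breed == "overall")].iloc[0]
        assert row.carriers == 155 and row.total == 1831
        assert row.freq == 0.085

    def test_printed_breed_frequency(self):
        groups, pm = self.build_counts([("Duolang", 63, 68)])
        tab = ov.haplogroup_frequencies(groups, pm)
        row = tab[(tab.haplogroup == "hap-1") & (tab.breed == "Duolang")].iloc[0]
        assert row.freq == 0.926

    def test_zero_carriers(self):
        groups, pm = self.build_counts([("b", 0, 10)])
        tab = ov.haplogroup_frequencies(groups, pm)
        row = tab[(tab.haplogroup == "hap-1") & (tab.breed == "b")].iloc[0]
        assert row.freq == 0.0

    def test_row_sums_equal_breed_totals(self):
        groups, pm = self.build_counts([("b1", 3, 8), ("b2", 5, 6)])
        tab = ov.haplogroup_frequencies(groups, pm)
        for breed, total in (("b1", 8), ("b2", 6)):
            sub = tab[tab.breed == breed]
            assert sub.carriers.sum() == total
            assert (sub.total == total).all()


class TestNetwork:
    def test_two_haplotypes_single_edge(self):
        rh = region_from_matrix(np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 0, 1]]))
        net = ov.build_network(rh)
        assert net.graph.number_of_nodes() == 2
        (u, v), = net.mst_edges
        assert net.graph.edges[u, v]["weight"] == 1
        counts = sorted(d["count"] for _, d in net.graph.nodes(data=True))
        assert counts == [2, 2]

    def test_star_topology(self):
        center = np.zeros(10, dtype=np.int8)
        rows = [center]
        for k in range(4):
            h = center.copy()
            h[k] = 1
            rows.append(h)
        rows.append(center)  # even haplotype count
        net = ov.build_network(region_from_matrix(np.array(rows)))
        center_label = sorted(net.graph.nodes)[0]
        degrees = dict(nx_degree(net))
        assert degrees[center_label] == 4
        assert net.total_mst_weight() == 4

    def test_mst_weight_equals_kruskal_oracle(self):
        rng = np.random.default_rng(12)
        rows = rng.integers(0, 2, (12, 25)).astype(np.int8)
        rh = region_from_matrix(rows)
        net = ov.build_network(rh)
        reps = {r.tobytes(): r for r in rows}
        uniq = [reps[k] for k in sorted(reps)]
        n = len(uniq)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                dist[i, j] = np.sum(uniq[i] != uniq[j])
        assert net.total_mst_weight() == mst_weight_oracle(dist)

    def test_multiplicities_sum_to_input(self):
        rng = np.random.default_rng(13)
        rows = rng.integers(0, 2, (20, 6)).astype(np.int8)
        net = ov.build_network(region_from_matrix(rows))
        assert sum(d["count"] for _, d in net.graph.nodes(data=True)) == 20

    def test_single_distinct_haplotype_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ov.build_network(region_from_matrix(np.zeros((4, 5), dtype=np.int8)))


def nx_degree(net):
    return [(n, sum(1 for e in net.mst_edges if n in e)) for n in net.graph.nodes]
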