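"""Dating formulas, superfamily/lineage classification, neighbor joining."""

import numpy as np
import pytest

from paleoevo import simulate as sim
from paleoevo.ltrclock import (AmbiguityError, DivergenceRecord, DomainHit,
                               LineageClassifier, SaturationError,
                               age_distribution, align_ltrs,
                               classify_superfamily, compute_lambda,
                               date_element, insertion_time, jc_distance,
                               nj_graph, nj_tree)


class TestJukesCantor:
    def test_zero_divergence_zero_distance(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_distance(0.05) == pytest.approx(0.0517447, abs=1e-6)

    @pytest.mark.parametrize("lam", [0.75, 0.8, 1.0])
    def test_saturation_raises(self, lam):
        with pytest.raises(SaturationError):
            jc_distance(lam)

    def test_correction_exceeds_raw_and_is_convex(self):
        grid = np.linspace(0.0, 0.7499, 1000)
        K = np.array([jc_distance(x) for x in grid])
        assert np.all(K >= grid)
        assert np.all(np.diff(K) > 0)  # strictly increasing
        assert np.all(np.diff(K, 2) > -1e-12)  # convex
        assert jc_distance(1e-6) / 1e-6 == pytest.approx(1.0, rel=1e-4)


class TestInsertionTime:
    def test_arithmetic(self):
        assert insertion_time(0.0) == 0.0
        assert insertion_time(0.014, 7e-9) == pytest.approx(1.0e6)

    def test_linearity(self):
        assert insertion_time(0.2, 7e-9) == pytest.approx(
            2 * insertion_time(0.1, 7e-9))

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            insertion_time(0.1, 0.0)


class TestLambda:
    def test_identical_sequences(self):
        a = "ACGT" * 75
        lam, sites, mism = compute_lambda(align_ltrs(a, a))
        assert (lam, sites, mism) == (0.0, 300, 0)

    def test_counting(self):
        a = "A" * 100
        b = "A" * 95 + "G" * 5
        lam, sites, mism = compute_lambda((a, b))
        assert (lam, sites, mism) == (0.05, 100, 5)

    def test_gap_and_ambiguity_columns_excluded(self):
        a = "ACGTN-AC"
        b = "ACCT-TNC"
        lam, sites, mism = compute_lambda((a, b))
        # columns with N or a gap in either row are excluded from both the
        # numerator and the denominator: 5 usable columns, 1 mismatch (G/C)
        assert sites == 5 and mism == 1 and lam == 0.2

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="usable"):
            compute_lambda(("NNN", "NNN"))


class TestDateElement:
    def test_full_chain_on_known_divergence(self):
        rng = sim.stage_rng(21, "date")
        cfg = sim.SimConfig(seed=21)
        ests = []
        for i in range(150):
            el = sim.simulate_ltr_element(2e6, cfg, rng=rng)
            t, L = len(el.tsd), el.ltr_length
            rec = date_element("e", el.seq[t:t + L], el.seq[-t - L:-t])
            assert rec.status == "ok"
            assert rec.T_years == pytest.approx(rec.K / (2 * 7e-9))
            ests.append(rec.T_years)
        assert np.mean(ests) == pytest.approx(2e6, rel=0.05)

    def test_saturated_element_never_dated(self):
        rng = sim.stage_rng(22, "sat")
        a = sim.random_genome({"x": 300}, 0.5, rng)["x"]
        b = a.translate(str.maketrans("ACGT", "CGTA"))  # 100% divergence
        rec = date_element("e", a, b)
        assert rec.status == "saturated"
        assert rec.K is None and rec.T_years is None

    def test_short_ltr_flagged(self):
        rec = date_element("e", "ACGTACGT", "ACGTACGT")
        assert rec.status == "too_short"


class TestClassifySuperfamily:
    def mk(self, order):
        return [DomainHit("e", d, 100 * i + 1, 100 * i + 30)
                for i, d in enumerate(order)]

    def test_copia_order(self):
        assert classify_superfamily(
            self.mk(["GAG", "PR", "INT", "RT", "RH"])) == "Ty1/copia"

    def test_gypsy_order(self):
        assert classify_superfamily(
            self.mk(["GAG", "PR", "RT", "RH", "INT"])) == "Ty3/gypsy"

    def test_missing_domains_unknown(self):
        assert classify_superfamily(self.mk(["RT"])) == "unknown"
        assert classify_superfamily([]) == "unknown"

    def test_duplicate_domain_is_ambiguous(self):
        hits = self.mk(["INT", "RT"]) + self.mk(["INT"])
        with pytest.raises(AmbiguityError):
            classify_superfamily(hits)

    def test_planted_elements_classify_correctly(self, sim_cfg):
        for fam in ("copia", "gypsy"):
            el = sim.simulate_ltr_element(0.0, sim_cfg, superfamily=fam, rng=5)
            hits = [DomainHit(el.element_id, name, s + 1, e)
                    for name, s, e in el.domains]
            expect = "Ty1/copia" if fam == "copia" else "Ty3/gypsy"
            assert classify_superfamily(hits) == expect


class TestNeighborJoining:
    # additive matrix from ((A:1,B:2):1,(C:3,D:4))
    D4 = np.array([[0, 3, 5, 6],
                   [3, 0, 6, 7],
                   [5, 6, 0, 7],
                   [6, 7, 7, 0]], dtype=float)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        g, root = nj_graph(d, ["A", "B", "C"])
        # l_A = (dAB + dAC - dBC)/2 = 1, l_B = 2, l_C = 3
        assert g["A"][root]["length"] == pytest.approx(1.0)
        assert g["B"][root]["length"] == pytest.approx(2.0)
        assert g["C"][root]["length"] == pytest.approx(3.0)

    def test_additive_four_taxon_tree_recovered_exactly(self):
        g, _ = nj_graph(self.D4, ["A", "B", "C", "D"])
        import networkx as nx

        path = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
        labels = ["A", "B", "C", "D"]
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert path[a][b] == pytest.approx(self.D4[i, j], abs=1e-9)
        # topology: A,B share an internal neighbor; C,D share another
        na = next(iter(g.neighbors("A")))
        assert "B" in g.neighbors(na) or na in g.neighbors(
            next(iter(g.neighbors("B"))))

    def test_unrooted_topology_invariant_under_label_permutation(self):
        perm = [2, 0, 3, 1]
        labels = ["A", "B", "C", "D"]
        d2 = self.D4[np.ix_(perm, perm)]
        l2 = [labels[i] for i in perm]
        import networkx as nx

        g1, _ = nj_graph(self.D4, labels)
        g2, _ = nj_graph(d2, l2)
        p1 = dict(nx.all_pairs_dijkstra_path_length(g1, weight="length"))
        p2 = dict(nx.all_pairs_dijkstra_path_length(g2, weight="length"))
        for a in labels:
            for b in labels:
                assert p1[a][b] == pytest.approx(p2[a][b], abs=1e-9)

    @staticmethod
    def random_additive_matrix(n, rng):
        """Leaf-to-leaf distances of a random tree (an additive metric)."""
        import networkx as nx

        g = nx.Graph()
        g.add_edge("t0", "h0", length=rng.uniform(0.1, 2))
        g.add_edge("t1", "h0", length=rng.uniform(0.1, 2))
        g.add_edge("t2", "h0", length=rng.uniform(0.1, 2))
        for i in range(3, n):
            u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
            w = g[u][v]["length"]
            split = rng.uniform(0.2, 0.8) * w
            hub = f"h{i}"
            g.remove_edge(u, v)
            g.add_edge(u, hub, length=split)
            g.add_edge(hub, v, length=w - split)
            g.add_edge(f"t{i}", hub, length=rng.uniform(0.1, 2))
        labels = [f"t{i}" for i in range(n)]
        lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
        d = np.array([[lengths[a][b] for b in labels] for a in labels])
        d = (d + d.T) / 2.0  # remove float jitter from path summation
        np.fill_diagonal(d, 0.0)
        return d, labels

    def test_matches_scikit_bio_on_additive_matrices(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        for _ in range(5):
            d, labels = self.random_additive_matrix(6, rng)
            n = len(labels)
            ours, _ = nj_graph(d, labels)
            theirs = skbio_nj(DistanceMatrix(d, labels))
            # compare unrooted leaf-to-leaf path lengths
            import networkx as nx

            p = dict(nx.all_pairs_dijkstra_path_length(ours, weight="length"))
            for i in range(n):
                for j in range(i + 1, n):
                    assert p[labels[i]][labels[j]] == pytest.approx(
                        theirs.find(labels[i]).distance(theirs.find(labels[j])),
                        abs=1e-6)

    def test_newick_output_parses(self):
        import dendropy

        nwk = nj_tree(self.D4, ["A", "B", "C", "D"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == \
               {"A", "B", "C", "D"}

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nj_graph(np.array([[0, 1], [1, 0]], float), ["A", "B"])
        bad = self.D4.copy()
        bad[0, 1] = 99  # asymmetric
        with pytest.raises(ValueError):
            nj_graph(bad, ["A", "B", "C", "D"])


class TestLineageAssignment:
    def test_identical_to_exemplar(self):
        refs = sim.lineage_exemplars(300, seed=1)
        clf = LineageClassifier(refs)
        assert clf.assign(refs["Tekay"]) == "Tekay"

    def test_equidistant_query_is_unknown(self):
        refs = {"X": "A" * 200, "Y": "C" * 200}
        clf = LineageClassifier(refs)
        assert clf.assign("A" * 100 + "C" * 100) == "unknown"

    def test_short_query_rejected(self):
        refs = sim.lineage_exemplars(300, seed=1)
        clf = LineageClassifier(refs)
        with pytest.raises(ValueError, match="too_short"):
            clf.assign("ACGT" * 10)

    def test_recovery_at_planted_divergence(self):
        refs = sim.lineage_exemplars(300, seed=2)
        clf = LineageClassifier(refs)
        rng = sim.stage_rng(9, "lineage")
        names = sorted(refs)
        correct = 0
        for i in range(50):
            name = names[i % len(names)]
            query = sim.mutate_jc(refs[name], 0.05, rng)
            correct += clf.assign(query) == name
        assert correct / 50 >= 0.95


class TestAgeDistribution:
    def mk(self, t, status="ok"):
        return DivergenceRecord("e", 300, 3, 0.01, 0.0101,
                                t if status == "ok" else None, status)

    def test_empty_input(self):
        hist, summary = age_distribution([], bin_width=0.5e6)
        assert len(hist) == 0 and summary["n_total"] == 0

    def test_counts_are_conserved(self):
        recs = ([self.mk(0.2e6)] * 3 + [self.mk(1.7e6)] * 2 +
                [self.mk(None, "saturated")] + [self.mk(None, "too_short")])
        hist, summary = age_distribution(recs, bin_width=0.5e6)
        assert hist["count"].sum() + summary["n_saturated"] + \
            summary["n_too_short"] == len(recs)
        assert hist.iloc[0]["count"] == 3

    def test_modal_bins_at_planted_ages(self):
        rng = sim.stage_rng(23, "hist")
        cfg = sim.SimConfig(seed=23)
        recs = []
        for age in (0.5e6, 5e6):
            for i in range(60):
                el = sim.simulate_ltr_element(age, cfg, rng=rng)
                t, L = len(el.tsd), el.ltr_length
                recs.append(date_element("e", el.seq[t:t + L],
                                         el.seq[-t - L:-t]))
        hist, _ = age_distribution(recs, bin_width=0.5e6)
        # the histogram is bimodal around the two planted ages: the best
        # bin near each age (within the sampling spread of lambda-hat)
        young = hist[hist["bin_start"] < 2.5e6]
        old = hist[hist["bin_start"] >= 2.5e6]
        assert young.loc[young["count"].idxmax(), "bin_start"] <= 1.0e6
        assert 3.5e6 <= old.loc[old["count"].idxmax(), "bin_start"] <= 6.0e6

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            age_distribution([], bin_width=0.0)
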