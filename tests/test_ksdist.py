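"""Codon alignment, Nei-Gojobori Ks/Ka with pathway oracle, 4dTv, peaks."""

import itertools

import numpy as np
import pytest

from paleoevo import simulate as sim
from paleoevo.ksdist import (CodonInputError, PeakCall, block_median_distances,
                             codon_align, detect_peaks, four_dtv, ng_distance,
                             pair_stats, wgd_report)
from paleoevo.synteny import SyntenyBlock

SENSE = sim._SENSE_CODONS


def random_cds(n_codons, rng):
    return "".join(SENSE[i] for i in rng.integers(0, len(SENSE), n_codons))


# ---------------------------------------------------------------------------
# independent Nei-Gojobori oracle built on Biopython translation

from Bio.Seq import Seq


def oracle_counts(cds_a, cds_b):
    """Site and difference counts by direct enumeration over the code."""
    syn_sites = 0.0
    sd = nd = 0.0
    n = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        n += 1
        for codon in (ca, cb):
            aa = str(Seq(codon).translate())
            s = 0.0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    mut = codon[:pos] + base + codon[pos + 1:]
                    if str(Seq(mut).translate()) == aa != "*":
                        s += 1 / 3
            syn_sites += s / 2
        if ca != cb:
            diff = [p for p in range(3) if ca[p] != cb[p]]
            paths = []
            for order in itertools.permutations(diff):
                cur, s_, n_, ok = ca, 0, 0, True
                for p in order:
                    nxt = cur[:p] + cb[p] + cur[p + 1:]
                    if str(Seq(nxt).translate()) == "*":
                        ok = False
                    if str(Seq(nxt).translate()) == str(Seq(cur).translate()):
                        s_ += 1
                    else:
                        n_ += 1
                    cur = nxt
                paths.append((s_, n_, ok))
            open_ = [(s_, n_) for s_, n_, ok in paths if ok] or \
                    [(s_, n_) for s_, n_, _ in paths]
            sd += sum(s_ for s_, _ in open_) / len(open_)
            nd += sum(n_ for _, n_ in open_) / len(open_)
    return syn_sites, 3 * n - syn_sites, sd, nd


class TestCodonAlign:
    def test_identical_cds_align_without_gaps(self):
        cds = "ATGGCTAAA"
        a, b = codon_align(cds, cds)
        assert a == b == cds

    def test_whole_codon_deletion_gives_one_triplet_gap(self):
        a = "ATGGCTAAAGGG"
        b = "ATGAAAGGG"  # GCT codon removed
        aa, bb = codon_align(a, b)
        assert aa == "ATGGCTAAAGGG"
        assert bb == "ATG---AAAGGG"

    def test_back_translation_preserves_codons(self):
        rng = np.random.default_rng(4)
        a, b = random_cds(40, rng), random_cds(40, rng)
        aa, bb = codon_align(a, b)
        assert aa.replace("-", "") == a
        assert bb.replace("-", "") == b
        for i in range(0, len(aa), 3):
            assert (aa[i:i + 3] == "---") == ("-" in aa[i:i + 3])

    def test_internal_stop_rejected(self):
        with pytest.raises(CodonInputError, match="stop"):
            codon_align("ATGTAAGGGAAA", "ATGTAAGGGAAA")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(CodonInputError, match="divisible"):
            codon_align("ATGC", "ATGC")


class TestNeiGojobori:
    def test_identical_sequences_have_zero_distances(self):
        cds = "ATGGCTAAAGGGTTT" * 8
        st = pair_stats(cds, cds)
        assert st.Ks == 0.0 and st.Ka == 0.0 and st.status == "ok"

    def test_toy_pair_hand_counted(self):
        # GGT GAT CAT vs GGC GAT CAT: one synonymous third-position change
        st = pair_stats("GGTGATCAT", "GGCGATCAT", min_codons=1)
        assert st.syn_sites == pytest.approx(5 / 3)
        assert st.nonsyn_sites == pytest.approx(22 / 3)
        assert st.syn_diffs == 1.0
        assert st.pS == pytest.approx(0.6)
        # Ks = -0.75 ln(1 - 0.8) = -0.75 ln 0.2
        assert st.Ks == pytest.approx(-0.75 * np.log(0.2), abs=1e-9)
        assert st.Ka == 0.0

    def test_symmetric_in_sequence_order(self):
        rng = np.random.default_rng(8)
        a, b = random_cds(50, rng), random_cds(50, rng)
        s1, s2 = pair_stats(a, b), pair_stats(b, a)
        for f in ("syn_sites", "nonsyn_sites", "syn_diffs", "nonsyn_diffs",
                  "pS", "pN", "fourfold_sites", "fourfold_tv"):
            assert getattr(s1, f) == pytest.approx(getattr(s2, f))

    def test_matches_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            a = random_cds(60, rng)
            # mutate a moderately so pairs are related but not identical
            b = sim.mutate_jc(a, 0.15, rng)
            if any(sim.CODON_AA[b[i:i + 3]] == "*"
                   for i in range(0, len(b), 3)):
                continue
            st = ng_distance(a, b)
            S, N, sd, nd = oracle_counts(a, b)
            assert st.syn_sites == pytest.approx(S)
            assert st.nonsyn_sites == pytest.approx(N)
            assert st.syn_diffs == pytest.approx(sd)
            assert st.nonsyn_diffs == pytest.approx(nd)

    def test_too_short_flagged(self):
        st = pair_stats("GGTGATCAT", "GGCGATCAT")  # 3 codons < 30
        assert st.status == "too_short"

    def test_saturated_flagged(self):
        # fourfold third positions all changed -> pS driven extremely high
        a = "GGT" * 60
        b = "GGA" * 60
        st = ng_distance(a, b, min_codons=30)
        assert st.pS >= 0.74999 and st.status == "saturated"
        assert st.Ks is None


class TestFourDTV:
    def test_identical_sequences(self):
        cds = "GGTGCTCCC" * 12
        n4, ntv, fdtv = four_dtv(cds, cds)
        assert n4 == 36 and ntv == 0 and fdtv == 0.0

    def test_transitions_only_give_zero(self):
        a = "GGT" * 50
        b = "GGC" * 50  # T->C transition at fourfold site
        assert four_dtv(a, b) == (50, 0, 0.0)

    def test_transversion_counting(self):
        a = "GGT" * 99 + "GGA"
        b = "GGT" * 99 + "GGT"  # one A<->T transversion among 100 sites
        n4, ntv, fdtv = four_dtv(a, b)
        assert (n4, ntv) == (100, 1) and fdtv == pytest.approx(0.01)

    def test_nonfourfold_and_mismatched_prefix_columns_ignored(self):
        # AAT (Asn, twofold) never counts; differing prefixes never count
        assert four_dtv("AAT", "AAA") == (0, 0, None)
        assert four_dtv("GGTCCT", "GGTGCT")[0] == 1


class TestBlockMedians:
    def mk_stats(self, ks, status="ok"):
        from paleoevo.ksdist import CodonPairStats

        return CodonPairStats("a", "b", 60, 45.0, 135.0, 1, 0, 0.1, 0.0,
                              ks, 0.0, 50, 0, 0.0, status)

    def test_median_over_ok_pairs(self):
        blk = SyntenyBlock("c1", "c2", [("a1", "b1"), ("a2", "b2"),
                                        ("a3", "b3")])
        stats = {("a1", "b1"): self.mk_stats(0.1),
                 ("a2", "b2"): self.mk_stats(0.2),
                 ("a3", "b3"): self.mk_stats(0.9)}
        df = block_median_distances([blk], stats)
        assert df.iloc[0]["median_ks"] == pytest.approx(0.2)
        assert not df.iloc[0]["low_support"]

    def test_saturated_pairs_excluded_and_low_support_flagged(self):
        blk = SyntenyBlock("c1", "c2", [("a1", "b1"), ("a2", "b2"),
                                        ("a3", "b3")])
        stats = {("a1", "b1"): self.mk_stats(0.3),
                 ("a2", "b2"): self.mk_stats(0.3),
                 ("a3", "b3"): self.mk_stats(None, "saturated")}
        df = block_median_distances([blk], stats)
        assert df.iloc[0]["n_ok"] == 2
        assert df.iloc[0]["median_ks"] == pytest.approx(0.3)
        assert df.iloc[0]["low_support"]


class TestDetectPeaks:
    def test_point_mass_single_peak(self):
        rng = np.random.default_rng(2)
        vals = 0.3 + rng.normal(0, 1e-4, 200)
        pk = detect_peaks(vals)
        assert len(pk.positions) == 1
        assert pk.positions[0] == pytest.approx(0.3, abs=0.01)

    def test_two_component_mixture_recovers_both_modes(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0.3, 0.05, 1000),
                               rng.normal(0.7, 0.05, 1000)])
        pk = detect_peaks(vals)
        assert len(pk.positions) == 2
        assert pk.positions[0] == pytest.approx(0.3, abs=0.05)
        assert pk.positions[1] == pytest.approx(0.7, abs=0.05)

    def test_uniform_values_mostly_peakless(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pk = detect_peaks(rng.uniform(0, 1, 500))
            hits += len(pk.positions) == 0
        assert hits >= 18  # >= 90% of seeds

    def test_invariant_to_ordering_and_duplication(self):
        rng = np.random.default_rng(5)
        vals = list(rng.normal(0.4, 0.05, 200))
        p1 = detect_peaks(vals)
        p2 = detect_peaks(list(reversed(vals)))
        p3 = detect_peaks(vals + vals)
        assert p1.positions == p2.positions
        assert p1.positions == pytest.approx(p3.positions, abs=0.02)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="50"):
            detect_peaks([0.3] * 49)


class TestWgdReport:
    def peaks(self, *positions):
        return PeakCall(positions=list(positions),
                        heights=[1.0] * len(positions),
                        bandwidth=0.05, n_values=500)

    def test_single_wgd_called_at_youngest_peak(self):
        depth = {"modal_depth": 2, "consistent": True}
        rep = wgd_report(depth, self.peaks(0.3))
        assert len(rep["events"]) == 1
        assert rep["events"][0]["event"] == "recent WGD"
        assert rep["events"][0]["distance"] == pytest.approx(0.3)

    def test_two_rounds_reported_young_to_old(self):
        depth = {"modal_depth": 2, "consistent": True}
        rep = wgd_report(depth, self.peaks(0.3, 0.7))
        assert [e["distance"] for e in rep["events"]] == [0.3, 0.7]
        assert rep["events"][1]["event"] == "older shared duplication"

    def test_no_signal(self):
        rep = wgd_report({"modal_depth": 1, "consistent": False},
                         self.peaks())
        assert rep["call"] == "no duplication signal"
        assert rep["events"] == []

    def test_missing_inputs_reported_as_gaps(self):
        rep = wgd_report(None, None)
        assert len(rep["gaps"]) == 2
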