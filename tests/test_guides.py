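"""sgRNA enumeration, ranking, T7 template reconstruction, cleavage prediction."""

import numpy as np
import pytest

from mxetools.guides import (
    SCAFFOLD_ANTISENSE_OLIGO,
    T7_PROMOTER,
    GuideCandidate,
    ScaffoldSpec,
    default_scaffold,
    enumerate_guides,
    predict_linearization,
    rank_guides,
    scaffold_clash,
    t7_template,
)
from mxetools.seqcore import DnaRecord, revcomp

import oracles


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestEnumerate:
    def test_no_gg_no_guides(self):
        rec = DnaRecord("x", "ATATATATATATATATATATATATATATATAT" * 3)
        assert enumerate_guides(rec, (0, len(rec))) == []

    def test_matches_naive_pam_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(100, 800))
            seq = _random_seq(rng, n)
            rec = DnaRecord("x", seq)
            lo, hi = 0, n
            got = sorted(
                (c.pam_pos, c.strand, c.spacer, c.cut_pos)
                for c in enumerate_guides(rec, (lo, hi))
            )
            assert got == oracles.naive_pam_guides(seq, lo, hi)

    def test_interval_flank_filter(self):
        rng = np.random.default_rng(23)
        seq = _random_seq(rng, 600)
        rec = DnaRecord("x", seq)
        inner = enumerate_guides(rec, (200, 300))
        flanked = enumerate_guides(rec, (200, 300), flank=50)
        assert {c.pam_pos for c in inner} <= {c.pam_pos for c in flanked}
        assert all(150 <= c.pam_pos < 350 for c in flanked)

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(29)
        seq = _random_seq(rng, 400)
        n = len(seq)
        fwd = enumerate_guides(DnaRecord("x", seq), (0, n))
        rev = enumerate_guides(DnaRecord("x", revcomp(seq)), (0, n))
        fwd_set = {(c.spacer, c.pam) for c in fwd}
        rev_set = {(c.spacer, c.pam) for c in rev}
        assert fwd_set == rev_set
        # cut coordinates mirror: cut' = n - cut
        fwd_cuts = sorted(c.cut_pos for c in fwd)
        rev_cuts = sorted(n - c.cut_pos for c in rev)
        assert fwd_cuts == rev_cuts

    def test_circular_wraps_origin(self):
        rng = np.random.default_rng(31)
        seq = _random_seq(rng, 300)
        # rotating a circle must not change the spacer/PAM inventory
        a = enumerate_guides(DnaRecord("x", seq, "circular"), (0, 300))
        rot = seq[150:] + seq[:150]
        b = enumerate_guides(DnaRecord("x", rot, "circular"), (0, 300))
        assert sorted((c.spacer, c.pam) for c in a) == sorted(
            (c.spacer, c.pam) for c in b
        )

    def test_gc_fields(self):
        c = GuideCandidate("GGGGGGGGGG" + "ATATATATAT", "TGG", +1, 100, 103)
        assert c.gc_5prime == 1.0 and c.gc_seed == 0.0


class TestRank:
    def _cand(self, spacer, cut=100, pam_pos=103):
        return GuideCandidate(spacer, "AGG", +1, cut, pam_pos)

    def test_high_seed_gc_first(self):
        low = self._cand("ATATATATAT" + "ATATGCATAT")
        high = self._cand("ATATATATAT" + "GCGCGCGCAT")
        ranked, excl = rank_guides([low, high])
        assert ranked[0] is high and not excl

    def test_low_5prime_gc_first(self):
        gc5 = self._cand("GCGCGCGCGC" + "GCGCGCGCGC")
        at5 = self._cand("ATATATATAT" + "GCGCGCGCGC")
        ranked, _ = rank_guides([gc5, at5])
        assert ranked[0] is at5

    def test_scaffold_clash_excluded(self):
        scaffold = default_scaffold()
        # spacer containing a 10-nt reverse complement of a scaffold segment
        seg = scaffold.rna.replace("U", "T")[20:30]
        spacer = ("ATATATATAT" + revcomp(seg))[:20]
        clash = scaffold_clash(spacer, scaffold)
        assert clash >= 10
        ranked, excl = rank_guides([self._cand(spacer)], clash_threshold=8)
        assert ranked == [] and spacer in excl
        assert "clash" in excl[spacer]

    def test_total_order_matches_comparator(self):
        rng = np.random.default_rng(37)
        cands = [
            self._cand(_random_seq(rng, 20), cut=int(rng.integers(0, 500)))
            for _ in range(30)
        ]
        scaffold = default_scaffold()
        ranked, excl = rank_guides(cands, scaffold, interval_mid=250)
        survivors = [c for c in cands if scaffold_clash(c.spacer, scaffold) < 8]
        expect = sorted(
            survivors,
            key=lambda c: (c.gc_5prime, -c.gc_seed, abs(c.cut_pos - 250), c.pam_pos),
        )
        assert [c.spacer for c in ranked] == [c.spacer for c in expect]
        # deterministic: same input, same order
        again, _ = rank_guides(cands, scaffold, interval_mid=250)
        assert [c.spacer for c in again] == [c.spacer for c in ranked]


class TestT7Template:
    def test_all_g_spacer_no_prefix(self):
        res = t7_template("G" * 20)
        assert not res["g_prepended"]
        assert res["sgrna"] == "G" * 20 + default_scaffold().rna
        assert res["sgrna_length"] == 20 + 83

    def test_non_g_spacer_prefixed(self):
        res = t7_template("ATGCATGCATGCATGCATGC")
        assert res["g_prepended"]
        assert res["sgrna"].startswith("GAUGC")
        assert res["sgrna_length"] == 21 + 83

    def test_default_scaffold_is_revcomp_of_printed_oligo(self):
        scaffold = default_scaffold()
        assert len(SCAFFOLD_ANTISENSE_OLIGO) == 83
        assert scaffold.rna == revcomp(SCAFFOLD_ANTISENSE_OLIGO).replace("T", "U")
        res = t7_template("G" * 20)
        assert res["sgrna"][-83:] == scaffold.rna

    def test_two_oligo_reconstructs_ultramer(self):
        spacer = "GTCGACTGCATGCATGCATG"
        full = t7_template(spacer, mode="full_ultramer")
        two = t7_template(spacer, mode="two_oligo")
        sense = two["sense_template"]
        # extension of the annealed pair yields the same duplex: scaffold
        # antisense + antisense of the promoter+spacer part == full ultramer
        promoter_spacer = sense[: len(sense) - 83]
        rebuilt = two["scaffold_antisense_oligo"] + revcomp(promoter_spacer)
        assert rebuilt == full["antisense_ultramer"]
        assert two["scaffold_antisense_oligo"] == SCAFFOLD_ANTISENSE_OLIGO
        assert len(two["promoter_spacer_oligo"]) == 60
        assert two["annealing_overlap"] == 60 - (len(T7_PROMOTER) + 20 - 1)

    def test_promoter_g_is_transcription_start(self):
        res = t7_template("GATTACAGATTACAGATTAC")
        assert res["sense_template"].startswith(T7_PROMOTER)
        # transcript begins at the promoter's terminal G
        assert res["sgrna"][0] == "G"

    def test_rejects_bad_spacer(self):
        with pytest.raises(Exception):
            t7_template("ATGN" * 5)


class TestPredictLinearization:
    def _plasmid_with_protospacers(self, rng, n, protos):
        seq = list(_random_seq(rng, n))
        for pos, proto in protos:
            seq[pos : pos + len(proto)] = list(proto)
        return DnaRecord("p", "".join(seq), "circular")

    def test_single_guide_linearizes(self):
        rng = np.random.default_rng(41)
        spacer = "GTACGTACGTACGTACGTAC"
        proto = spacer + "TGG"
        plasmid = self._plasmid_with_protospacers(rng, 15000, [(4000, proto)])
        g = GuideCandidate(spacer, "TGG", +1, 0, 0)
        fs = predict_linearization(plasmid, [g])
        assert fs.lengths == (15000,) and fs.cut_count == 1

    def test_two_guides_release_gap(self):
        rng = np.random.default_rng(43)
        s1, s2 = "GTACGTACGTACGTACGTAC", "GATCGATCGATCGTTACGTA"
        plasmid = self._plasmid_with_protospacers(
            rng, 15000, [(1000, s1 + "AGG"), (3000 - 17, s2 + "CGG")]
        )
        g1 = GuideCandidate(s1, "AGG", +1, 0, 0)
        g2 = GuideCandidate(s2, "CGG", +1, 0, 0)
        fs = predict_linearization(plasmid, [g1, g2])
        # cuts at 1017 and 3000: fragments 1983 and 13017
        assert sorted(fs.lengths) == [1983, 13017]
        assert sum(fs.lengths) == 15000

    def test_single_mismatch_not_tolerated(self):
        rng = np.random.default_rng(47)
        spacer = "GTACGTACGTACGTACGTAC"
        plasmid = self._plasmid_with_protospacers(rng, 5000, [(1000, spacer + "TGG")])
        bad = spacer[:10] + ("A" if spacer[10] != "A" else "C") + spacer[11:]
        g = GuideCandidate(bad, "TGG", +1, 0, 0)
        with pytest.raises(Exception, match="no exact"):
            predict_linearization(plasmid, [g])

    def test_multiple_matches_rejected(self):
        rng = np.random.default_rng(53)
        spacer = "GTACGTACGTACGTACGTAC"
        proto = spacer + "TGG"
        plasmid = self._plasmid_with_protospacers(
            rng, 8000, [(1000, proto), (5000, proto)]
        )
        g = GuideCandidate(spacer, "TGG", +1, 0, 0)
        with pytest.raises(Exception, match="multiple"):
            predict_linearization(plasmid, [g])

    def test_fragment_sum_conservation(self):
        rng = np.random.default_rng(59)
        for trial in range(5):
            n = int(rng.integers(4000, 20000))
            s1, s2 = _random_seq(rng, 20), _random_seq(rng, 20)
            p1, p2 = sorted(rng.choice(n - 200, size=2, replace=False))
            if p2 - p1 < 30:
                continue
            plasmid = self._plasmid_with_protospacers(
                rng, n, [(int(p1), s1 + "AGG"), (int(p2), s2 + "TGG")]
            )
            try:
                fs = predict_linearization(
                    plasmid,
                    [
                        GuideCandidate(s1, "AGG", +1, 0, 0),
                        GuideCandidate(s2, "TGG", +1, 0, 0),
                    ],
                )
            except Exception:
                continue  # random spacer happened to multi-match
            assert sum(fs.lengths) == n
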