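"""uTIS counting, uORF rules, TIS-context patterns, association statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rbpreg import features as ft
from rbpreg.features import (
    NEAR_COGNATE_STARTS,
    STOP_CODONS,
    UTIS,
    TranscriptAnnotation,
    assoc_fisher,
    assoc_spearman,
    count_utis,
    detect_uorfs,
    distance_profile,
    fisher_exact_2x2,
    ingest_feature_table,
    match_tis_patterns,
    set_enrichment,
)


def ann_from(utr5, utis=(), cds="AUG" + "GCU" * 4 + "UAA", utr3="ACGUACGU", tid="T1"):
    return TranscriptAnnotation(
        transcript_id=tid, utr5=utr5, cds=cds, utr3=utr3,
        utis_list=[UTIS(*u) for u in utis],
    )


class TestCountUtis:
    def test_empty(self):
        ann = ann_from("ACGU" * 10)
        assert count_utis(ann) == 0
        assert count_utis(ann, max_distance=50) == 0

    def test_distance_window(self):
        # 5'UTR of length 430; uTISs at distances 30, 120, 400 from the aTIS
        L = 430
        utis = [(L - 30, "AUG", True), (L - 120, "CUG", False), (L - 400, "AUG", True)]
        ann = ann_from("A" * L, utis)
        assert count_utis(ann, max_distance=50) == 1
        assert count_utis(ann, max_distance=150) == 2
        assert count_utis(ann) == 3

    def test_canonical_filter(self):
        L = 60
        utis = [(10, "AUG", True), (20, "CUG", False), (30, "AUG", True)]
        ann = ann_from("A" * L, utis)
        assert count_utis(ann, canonical_filter="canonical") == 2
        assert count_utis(ann, canonical_filter="noncanonical") == 1

    def test_monotone_in_distance(self, fixture_data):
        for ann in list(fixture_data["annotations"].values())[:20]:
            prev = -1
            for d in (0, 50, 100, 200, 400, math.inf):
                c = count_utis(ann, max_distance=d)
                assert c >= prev
                prev = c

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            count_utis(ann_from("ACGU" * 5), max_distance=-1)


def brute_force_uorfs(ann, min_len=9, start_codons=None):
    """Independent oracle: enumerate the rules directly on the transcript."""
    if start_codons is None:
        start_codons = {"AUG", *NEAR_COGNATE_STARTS}
    seq = ann.utr5 + ann.cds + ann.utr3
    atis = len(ann.utr5)
    main_stop_start = atis + len(ann.cds) - 3
    found = []
    for u in ann.utis_list:
        if u.codon not in start_codons:
            continue
        s = u.offset
        stops = [i for i in range(s, len(seq) - 2, 3) if seq[i:i + 3] in STOP_CODONS]
        if (atis - s) % 3 != 0:
            if stops and stops[0] + 3 - s >= min_len:
                found.append((s, stops[0] + 3, "out_of_frame"))
        else:
            pre = [i for i in stops if i + 3 <= atis]
            post = [i for i in stops if i >= main_stop_start + 3]
            if pre and pre[0] + 3 - s >= min_len:
                found.append((s, pre[0] + 3, "in_frame_pre"))
            elif not pre and post and post[0] + 3 - s >= min_len:
                found.append((s, post[0] + 3, "in_frame_post"))
    return found


class TestDetectUorfs:
    def test_out_of_frame_minimal_nine_nt(self):
        # uTIS at offset 1 (out of frame for any aTIS at multiple-of-3 - 1)
        utr5 = "C" + "AUGAAAUAA" + "CC"  # 12 nt; aTIS at 12; uTIS offset 1
        ann = ann_from(utr5, utis=[(1, "AUG", True)])
        assert (12 - 1) % 3 != 0
        uorfs = detect_uorfs(ann)
        assert len(uorfs) == 1
        assert uorfs[0].length == 9
        assert uorfs[0].frame_class == "out_of_frame"

    def test_out_of_frame_six_nt_rejected(self):
        utr5 = "C" + "AUGUAA" + "CCCCC"  # ORF span 6 nt < 9
        ann = ann_from(utr5, utis=[(1, "AUG", True)])
        assert detect_uorfs(ann) == []

    def test_in_frame_stop_before_atis(self):
        # aTIS at 12; uTIS at 0 in frame; stop at 6..9 entirely before aTIS
        utr5 = "AUGAAAUAGCCC"
        ann = ann_from(utr5, utis=[(0, "AUG", True)])
        uorfs = detect_uorfs(ann)
        assert len(uorfs) == 1 and uorfs[0].frame_class == "in_frame_pre"
        assert uorfs[0].length == 9

    def test_in_frame_stop_only_after_main_stop(self):
        # in-frame uTIS, no stop in the remaining UTR or CDS frame; first
        # in-frame stop lies beyond the main stop codon
        utr5 = "AUGCCC"  # uTIS at 0, aTIS at 6 (in frame)
        cds = "AUG" + "GCU" * 3 + "UAA"
        utr3 = "UAAACGU"  # in-frame stop right after the main stop
        ann = ann_from(utr5, utis=[(0, "AUG", True)], cds=cds, utr3=utr3)
        uorfs = detect_uorfs(ann)
        assert len(uorfs) == 1 and uorfs[0].frame_class == "in_frame_post"

    def test_unknown_start_codon_skipped(self):
        ann = ann_from("CCAGGAAAUAACC", utis=[(2, "AGG", False)])
        assert detect_uorfs(ann) == []

    def test_matches_three_frame_enumeration_oracle_on_random_utrs(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGU"))
        starts = ["AUG", *NEAR_COGNATE_STARTS]
        for _ in range(300):
            L = int(rng.integers(12, 120))
            utr5 = "".join(rng.choice(bases, size=L))
            n_codons = int(rng.integers(2, 8))
            cds = "AUG" + "".join(
                "".join(rng.choice(bases, size=3)) for _ in range(n_codons)
            ) + "UAA"
            utr3 = "".join(rng.choice(bases, size=int(rng.integers(0, 60))))
            # declare every start-codon occurrence in the 5'UTR as a uTIS
            utis = [
                UTIS(i, utr5[i:i + 3], utr5[i:i + 3] == "AUG")
                for i in range(L - 2)
                if utr5[i:i + 3] in starts
            ]
            ann = TranscriptAnnotation("T", utr5, cds, utr3, utis)
            got = [(o.start, o.stop_end, o.frame_class) for o in detect_uorfs(ann)]
            assert got == brute_force_uorfs(ann)


class TestTisPatterns:
    def _flags(self, context6, cds_head):
        # cds_head is 4 nt (AUG + the +4 base); pad to a multiple of 3
        ann = ann_from("ACGU" * 3 + context6, cds=cds_head + "CU" + "GCU" * 2 + "UAA")
        return match_tis_patterns(ann)

    def test_kozak_with_a_purine(self):
        assert self._flags("GCCACC", "AUGG")["kozak_match"] == 1

    def test_kozak_with_g_purine(self):
        assert self._flags("GCCGCC", "AUGG")["kozak_match"] == 1

    def test_kozak_fails_with_pyrimidine(self):
        assert self._flags("GCCUCC", "AUGG")["kozak_match"] == 0

    def test_minus3_pyrimidine_fails_regardless_of_plus4(self):
        flags = self._flags("GCCCCC", "AUGG")
        assert flags["minus3R_plus4G"] == 0

    def test_minus3r_plus4g(self):
        assert self._flags("UUUAUU", "AUGG")["minus3R_plus4G"] == 1
        assert self._flags("UUUAUU", "AUGC")["minus3R_plus4G"] == 0

    def test_tis_motif(self):
        # RYMRMV AUG GC: e.g. A C A G A A AUG G C
        ann = ann_from("ACGU" + "ACAGAA", cds="AUGGC" + "U" + "GCU" * 2 + "UAA")
        assert match_tis_patterns(ann)["tis_motif_match"] == 1

    def test_truncated_window_undefined(self):
        ann = ann_from("ACG", cds="AUG" + "GCU" * 2 + "UAA")
        flags = match_tis_patterns(ann)
        assert flags["kozak_match"] is None
        assert flags["tis_motif_match"] is None


class TestIngestFeatureTable:
    def test_partial_coverage(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("gene\thalf_life\nG1\t2.5\nG2\t4.0\n")
        out = ingest_feature_table(p, ["G1", "G2", "G3", "G4"])
        assert out.loc["G1", "half_life"] == 2.5
        assert out["half_life"].notna().sum() == 2

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("gene\tv\nG1\t1\nG1\t2\n")
        with pytest.raises(ValueError, match="G1"):
            ingest_feature_table(p, ["G1"])

    def test_numeric_parse_failure_reports_line(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("gene\tv\nG1\t1.0\nG2\toops\n")
        with pytest.raises(ValueError, match="line 3"):
            ingest_feature_table(p, ["G1", "G2"])

    def test_no_overlap_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("gene\tv\nX1\t1.0\n")
        with pytest.raises(ValueError, match="overlap"):
            ingest_feature_table(p, ["G1"])


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(12, dtype=float)
        rho, p = assoc_spearman(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = assoc_spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_ties_equal_pearson_of_average_ranks(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 40).astype(float)  # heavy ties
        y = rng.normal(size=40)
        rho, _ = assoc_spearman(x, y)
        ref = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(ref, rel=1e-9)

    def test_constant_feature_flagged(self):
        rho, p = assoc_spearman(np.ones(15), np.arange(15.0))
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="complete pairs"):
            assoc_spearman(np.arange(5.0), np.arange(5.0))


class TestDistanceProfile:
    def test_cumulative_counts_monotone(self, fixture_data):
        ann = fixture_data["annotations"]
        genes = list(ann)
        imp = pd.Series(np.random.default_rng(2).normal(size=len(genes)), index=genes)
        prof = distance_profile(ann, imp, (50, 100, 200, 400))
        assert (prof["n_utis"].diff().dropna() >= 0).all()

    def test_planted_distal_utis_drive_rising_correlation(self):
        """uTISs present only in high-improvement genes and only beyond
        200 nt: rho(d) undefined/weak at small d, strong and significant at
        large d."""
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(60)]
        imp = pd.Series(rng.normal(size=60), index=genes)
        ann = {}
        for g in genes:
            L = 400
            utis = []
            if imp[g] > 0:  # high-improvement genes carry distal uTISs
                utis = [UTIS(int(off), "AUG", True) for off in rng.integers(3, L - 250, 2)]
            ann[g] = ann_from("A" * L, tid=g)
            ann[g].utis_list = utis
        prof = distance_profile(ann, imp, (50, 150, 300, 400)).set_index("distance")
        assert not prof.loc[50, "defined"] or prof.loc[50, "n_utis"] == 0
        assert prof.loc[400, "rho"] > 0.5
        assert prof.loc[400, "p"] < 1e-4

    def test_no_utis_all_undefined(self):
        ann = {"G1": ann_from("ACGU" * 30, tid="G1"), "G2": ann_from("ACGU" * 30, tid="G2")}
        imp = pd.Series([0.1, 0.2], index=["G1", "G2"])
        prof = distance_profile(ann, imp, (100, 200))
        assert (~prof["defined"]).all()


def brute_force_fisher(a, b, c, d):
    """Exact two-sided p by direct factorial enumeration (math.comb)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_hand_enumerated_one_sided_table(self):
        # [[3,1],[1,3]]: one-sided enrichment p = 17/70
        _, _, p_enr, _ = assoc_fisher(
            informative_genes=[f"i{k}" for k in range(4)],
            feature_genes=["i0", "i1", "i2", "o0"],
            universe=[f"i{k}" for k in range(4)] + [f"o{k}" for k in range(4)],
        )
        assert p_enr == pytest.approx(17 / 70)

    def test_feature_equals_universe_degenerate(self):
        universe = [f"g{k}" for k in range(10)]
        odds, p2, p_enr, table = assoc_fisher(universe[:4], universe, universe)
        assert p2 == pytest.approx(1.0)
        assert math.isinf(odds) or math.isnan(odds)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, 4)
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(brute_force_fisher(int(a), int(b), int(c), int(d)), rel=1e-9)

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, 4))
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert p == pytest.approx(ref, rel=1e-7, abs=1e-12)


class TestSetEnrichment:
    def test_category_equals_universe_p_one(self):
        universe = [f"g{k}" for k in range(12)]
        out = set_enrichment(universe[:5], {"all": universe}, universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_single_category_matches_fisher_one_sided(self):
        universe = [f"g{k}" for k in range(30)]
        hits = universe[:8]
        cat = universe[4:16]
        out = set_enrichment(hits, {"c": cat}, universe)
        _, _, p_enr, _ = assoc_fisher(hits, cat, universe)
        row = out.iloc[0]
        if row["direction"] == "enriched":
            assert row["p"] == pytest.approx(p_enr, rel=1e-9)

    def test_depletion_reported(self):
        universe = [f"g{k}" for k in range(40)]
        hits = universe[:20]
        cat = universe[25:]  # disjoint from hits -> depleted
        out = set_enrichment(hits, {"c": cat}, universe)
        assert out.iloc[0]["direction"] == "depleted"
        assert out.iloc[0]["fold"] < 1
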