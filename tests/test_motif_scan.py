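import itertools

import numpy as np
import pytest

from nlr_evolkit.motif_scan import (
    NB_MOTIF_ORDER,
    MotifHit,
    MotifModel,
    NbDomainCall,
    _type_label,
    annotate_protein,
    build_profile_from_alignment,
    classify_architecture,
    detect_coiled_coil,
    detect_lrr,
    extract_nb_domain,
    is_full_type,
    scan_profile,
    scan_sd_domain,
)
from nlr_evolkit.synthetic_data import make_nlr_protein, make_subgroup_core


def _random_protein(rng, n):
    return "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=n))


class TestScanProfile:
    def test_planted_consensus_yields_exactly_one_covering_hit(self, models):
        rng = np.random.default_rng(0)
        m = models["P-loop"]
        left = _random_protein(rng, 80)
        prot = left + m.consensus + _random_protein(rng, 80)
        hits = scan_profile(prot, m)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (81, 80 + m.width)

    def test_shuffled_proteins_rarely_hit(self, models):
        # calibration contract: >= 99% of 500 shuffles give zero hits
        rng = np.random.default_rng(1)
        m = models["kinase-2"]
        seq = list(_random_protein(rng, 60) + m.consensus * 3 +
                   _random_protein(rng, 180))
        with_hits = 0
        for _ in range(500):
            rng.shuffle(seq)
            if scan_profile("".join(seq), m):
                with_hits += 1
        assert with_hits <= 5

    def test_degenerate_empty_model_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("bad", "major", np.empty((0, 20)), 0.0)

    def test_protein_shorter_than_width_gives_no_hits(self, models):
        assert scan_profile("MK", models["P-loop"]) == []


class TestCoiledCoil:
    @staticmethod
    def _oracle_score(seq, window=28):
        """Independent straightforward implementation of the heptad scan:
        explicit loops over windows and frames, weighted geometric mean."""
        from nlr_evolkit.motif_scan import _AA_IDX, _AD_WEIGHT, _CC_TABLE
        best = 0.0
        for s in range(len(seq) - window + 1):
            for frame in range(7):
                logsum = 0.0
                wsum = 0.0
                for k in range(window):
                    pos = (k + frame) % 7
                    w = _AD_WEIGHT if pos in (0, 3) else 1.0
                    p = _CC_TABLE[pos, _AA_IDX.get(seq[s + k], 20)]
                    logsum += w * np.log(max(p, 1e-9))
                    wsum += w
                best = max(best, float(np.exp(logsum / wsum)))
        return best

    def test_ideal_heptad_repeat_detected(self):
        seq = "LAELEQK" * 5
        prob, per_res, present = detect_coiled_coil(seq)
        assert present and prob > 0.9
        assert len(per_res) == len(seq)

    def test_score_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for seq in ["LAELEQK" * 5, _random_protein(rng, 40), "P" * 30 + "LAELEQK" * 2]:
            from nlr_evolkit.motif_scan import _cc_window_scores, _encode
            mine = float(_cc_window_scores(_encode(seq), 28).max())
            assert mine == pytest.approx(self._oracle_score(seq), rel=1e-9)

    def test_poly_proline_is_not_a_coil(self):
        prob, _, present = detect_coiled_coil("P" * 50)
        assert not present and prob < 0.01

    def test_short_protein_degenerate_output(self):
        prob, per_res, present = detect_coiled_coil("MKVLWAALLG")
        assert (prob, len(per_res), present) == (0.0, 0, False)

    def test_window_must_be_a_lupas_window(self):
        with pytest.raises(ValueError):
            detect_coiled_coil("A" * 50, window=20)


class TestLrr:
    def test_planted_tandem_units_detected(self, models):
        rng = np.random.default_rng(2)
        unit = models["LRR-unit"].consensus
        prot = _random_protein(rng, 50) + (unit + "ARND") * 5 + _random_protein(rng, 30)
        present, hits = detect_lrr(prot)
        assert present
        assert len(hits) >= 3

    def test_nb_only_protein_has_no_lrr(self, models):
        core = make_subgroup_core("t", "cc", np.random.default_rng(5), models=models)
        prot, _ = make_nlr_protein("g", "N_cc", core, 0.0, np.random.default_rng(6))
        present, _ = detect_lrr(prot)
        assert not present

    def test_tiny_peptide_is_negative(self):
        assert detect_lrr("MKVLA") == (False, [])


class TestExtractNbDomain:
    def _hit(self, name, start, width=8, score=20.0):
        return MotifHit(name, start, start + width - 1, score)

    def test_all_eight_motifs_in_order(self):
        hits = [self._hit(nm, 1 + 30 * i) for i, nm in enumerate(NB_MOTIF_ORDER)]
        nb = extract_nb_domain("A" * 300, hits)
        assert nb.nb_present
        assert nb.major_count == 4 and nb.minor_count == 4
        assert nb.nb_span == (1, hits[-1].end)

    def test_single_major_motif_still_counts(self):
        nb = extract_nb_domain("A" * 50, [self._hit("MHDV", 10)])
        assert nb.nb_present and nb.major_count == 1 and nb.minor_count == 0

    def test_minor_only_hits_do_not_make_an_nb(self):
        nb = extract_nb_domain("A" * 50, [self._hit("RNBS-A", 10)])
        assert not nb.nb_present

    def test_chain_selection_matches_enumeration_oracle(self):
        # tandem NB: two P-loops plus scattered motifs; oracle enumerates all
        # order-consistent subsets
        from nlr_evolkit.motif_scan import _MOTIF_RANK
        rng = np.random.default_rng(3)
        hits = [
            self._hit("P-loop", 1, score=15.0),
            self._hit("kinase-2", 40, score=18.0),
            self._hit("P-loop", 80, score=22.0),
            self._hit("GLPL", 120, score=12.0),
            self._hit("RNBS-B", 60, score=9.0),
            self._hit("MHDV", 150, score=11.0),
        ]

        def oracle_best(hs):
            hs = sorted(hs, key=lambda h: h.start)
            best = 0.0
            for r in range(1, len(hs) + 1):
                for combo in itertools.combinations(hs, r):
                    ranks = [_MOTIF_RANK[h.motif_name] for h in combo]
                    starts = [h.start for h in combo]
                    ends = [h.end for h in combo]
                    ok = all(ranks[i] < ranks[i + 1] and ends[i] < starts[i + 1]
                             for i in range(len(combo) - 1))
                    if ok:
                        best = max(best, sum(h.score for h in combo))
            return best

        nb = extract_nb_domain("A" * 200, hits)
        assert sum(h.score for h in nb.chain) == pytest.approx(oracle_best(hits))
        # the dropped P-loop resurfaces as a secondary (tandem) NB chain
        assert any(h.motif_name == "P-loop" for h in nb.secondary)

    def test_out_of_order_chain_keeps_best_consistent_subset(self):
        hits = [self._hit("MHDV", 1, score=30.0), self._hit("P-loop", 50, score=10.0)]
        nb = extract_nb_domain("A" * 100, hits)
        names = [h.motif_name for h in nb.chain]
        assert names in (["MHDV"], ["P-loop"])
        assert sum(h.score for h in nb.chain) == 30.0


class TestTyping:
    def test_decision_table_is_total_and_deterministic(self):
        for tir, cc, lrr in itertools.product([False, True], repeat=3):
            for lineage in ("tir", "cc", "unassigned"):
                label = _type_label(tir, cc and not tir, lrr, lineage)
                assert isinstance(label, str) and label

    @pytest.mark.parametrize("tir,cc,lrr,lineage,expected", [
        (True, False, True, "tir", "TNL"),
        (False, True, True, "cc", "CNL"),
        (False, True, False, "cc", "CN"),
        (True, False, False, "tir", "TN"),
        (False, False, True, "tir", "NL_tir"),
        (False, False, False, "cc", "N_cc"),
        (True, True, True, "tir", "TNL"),   # TIR wins over CC
    ])
    def test_examples(self, tir, cc, lrr, lineage, expected):
        nb = NbDomainCall(True, (1, 200), 4, 4)
        call = classify_architecture("g", nb, tir, cc, lrr, lineage)
        assert call.type_label == expected

    def test_requires_nb_domain(self):
        nb = NbDomainCall(False, None, 0, 0)
        with pytest.raises(ValueError):
            classify_architecture("g", nb, False, False, False)


class TestFullType:
    def _call(self, span_len, majors, minors):
        return NbDomainCall(True, (1, span_len), majors, minors)

    @pytest.mark.parametrize("span,majors,minors,expected", [
        (200, 3, 3, True),
        (159, 4, 4, False),
        (300, 2, 4, False),
        (160, 3, 3, True),
        (300, 4, 2, False),
    ])
    def test_boundaries(self, span, majors, minors, expected):
        assert is_full_type(self._call(span, majors, minors)) is expected

    def test_monotone_in_motif_evidence(self):
        # adding a motif never flips full-type from true to false
        for span in (160, 200):
            for majors in range(3, 5):
                for minors in range(3, 5):
                    base = is_full_type(self._call(span, majors, minors))
                    assert base
                    if majors < 4:
                        assert is_full_type(self._call(span, majors + 1, minors))
                    if minors < 4:
                        assert is_full_type(self._call(span, majors, minors + 1))


class TestSdDomain:
    def test_planted_sd_upstream_of_cc_found(self, models):
        core = make_subgroup_core("s", "cc", np.random.default_rng(9),
                                  has_sd=True, models=models)
        prot, truth = make_nlr_protein("g", "CNL", core, 0.0, np.random.default_rng(1))
        nb_start = truth.nb_span[0]
        present, hit = scan_sd_domain(prot, models["SD-core"], nb_start)
        assert present and hit.end < nb_start

    def test_sd_like_match_after_nb_does_not_count(self, models):
        rng = np.random.default_rng(4)
        seq = _random_protein(rng, 60) + models["SD-core"].consensus
        present, _ = scan_sd_domain(seq, models["SD-core"], nb_start=10)
        assert not present

    def test_requires_nb_position(self, models):
        with pytest.raises(ValueError):
            scan_sd_domain("MKV", models["SD-core"], nb_start=0)


class TestProfileBuilder:
    def test_consensus_scores_its_own_consensus_maximally(self):
        m = build_profile_from_alignment(["GKTTLA", "GKTTLA"], "t", "major")
        from nlr_evolkit.motif_scan import _encode, _window_scores
        scores = _window_scores(_encode("AAGKTTLAAA"), m.pssm)
        assert int(np.argmax(scores)) == 2

    def test_all_gap_column_dropped(self):
        m = build_profile_from_alignment(["GK-TT", "GK-TT", "GK-TT"], "t", "major")
        assert m.width == 4

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile_from_alignment(["GKTT", "GKT"], "t", "major")

    def test_cutoff_reproducible_under_fixed_seed(self):
        a = build_profile_from_alignment(["GKTTLA", "GKSTLA"], "t", "major",
                                         calibration_seed=11)
        b = build_profile_from_alignment(["GKTTLA", "GKSTLA"], "t", "major",
                                         calibration_seed=11)
        assert a.score_cutoff == b.score_cutoff


class TestArchitectureRecall:
    def test_noise_free_recall_is_exact_for_every_type(self, models):
        rng = np.random.default_rng(12)
        for lineage, labels in (("tir", ["TNL", "TN"]), ("cc", ["CNL", "CN"])):
            core = make_subgroup_core(f"c-{lineage}", lineage, rng, models=models)
            for label in labels:
                prot, truth = make_nlr_protein("g", label, core, 0.0, rng)
                call = annotate_protein(prot, models)
                assert call is not None
                assert call.type_label == label
                assert call.full_type

    def test_counting_identity_tir_plus_cc_partitions_total(self, pipeline_result):
        tally = pipeline_result["type_tally"]
        for sp, row in tally.counts.items():
            tir_side = row["TNL"] + row["NL_tir"] + row["TN"] + row["N_tir"]
            cc_side = row["CNL"] + row["NL_cc"] + row["CN"] + row["N_cc"]
            assert tir_side + cc_side == tally.total[sp]
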