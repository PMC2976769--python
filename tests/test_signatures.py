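import itertools
import math

import numpy as np
import pytest

from ghmotif.errors import GHMotifError
from ghmotif.io import ALPHABET, AlignedFamily
from ghmotif.signatures import (
    NEG_INF,
    ProfileModel,
    build_logo,
    build_profile,
    calibrate_threshold,
    evaluate_search,
    score_sequence,
)
from ghmotif.synthetic import MsaSpec, generate_msa, generate_sequence_db
from oracles import brute_force_glocal


def fam(rows):
    ids = [f"s{i}" for i in range(len(rows))]
    return AlignedFamily("t", ids, rows, ids[0])


class TestLogo:
    def test_invariant_column_full_information(self):
        logo = build_logo(fam(["W", "W", "W"]))
        assert logo.information[0] == pytest.approx(math.log2(20))
        assert logo.consensus == "W"

    def test_two_state_column(self):
        logo = build_logo(fam(["A", "C"]))
        assert logo.information[0] == pytest.approx(math.log2(20) - 1.0)

    def test_all_gap_position_flagged_zero(self):
        logo = build_logo(fam(["A-", "C-"]))
        assert logo.information[1] == 0.0
        assert logo.flagged[1]

    def test_frequencies_sum_to_one(self):
        msa, truth = generate_msa(MsaSpec(seed=2))
        block = msa.slice_columns(truth.motif_start, truth.motif_end + 1)
        logo = build_logo(block)
        np.testing.assert_allclose(logo.frequencies.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(logo.information >= 0)
        assert np.all(logo.information <= math.log2(20) + 1e-12)


class TestBuildProfile:
    def test_single_sequence_no_pseudocount(self):
        prof = build_profile(fam(["ACD"]), pseudocount=0.0)
        for p, a in enumerate("ACD"):
            emission = np.exp(prof.log_odds[p]) * prof.background
            assert emission[ALPHABET.index(a)] == pytest.approx(1.0)

    def test_unseen_residue_neg_inf_when_alpha_zero(self):
        prof = build_profile(fam(["A"]), pseudocount=0.0)
        assert prof.log_odds[0, ALPHABET.index("W")] == NEG_INF

    def test_large_pseudocount_flattens_log_odds(self):
        prof = build_profile(fam(["AAAA"]), pseudocount=1e9)
        assert np.max(np.abs(prof.log_odds)) < 1e-6

    def test_declared_pseudocount_arithmetic(self):
        # all-Trp column, total weight 10, alpha=1, uniform background:
        # emission(W) = (10 + 0.05) / 11
        msa = fam(["W"] * 10)
        prof = build_profile(msa, pseudocount=1.0)
        emission = np.exp(prof.log_odds[0]) * prof.background
        assert emission[ALPHABET.index("W")] == pytest.approx(10.05 / 11)


class TestScoreSequence:
    def test_consensus_scores_positionwise_maximum(self):
        msa, truth = generate_msa(MsaSpec(seed=5))
        block = msa.slice_columns(truth.motif_start, truth.motif_end + 1)
        prof = build_profile(block)
        score, start = score_sequence(prof, prof.consensus)
        assert score == pytest.approx(prof.consensus_score())
        assert start == 0

    def test_start_position_reported(self):
        prof = build_profile(fam(["WWWW"] * 5))
        seq = "ACDE" + "WWWW" + "ACDE"
        score, start = score_sequence(prof, seq)
        assert start == 4

    def test_empty_sequence_sentinel(self):
        prof = build_profile(fam(["ACD"]))
        assert score_sequence(prof, "") == (NEG_INF, None)

    def test_dp_equals_exhaustive_oracle(self):
        """Full equivalence with alignment enumeration on small instances."""
        rng = np.random.default_rng(0)
        alphabet4 = "ACDE"
        n_checked = 0
        for m in range(1, 5):
            log_odds = rng.normal(0.0, 2.0, size=(m, 20))
            prof = ProfileModel("t", log_odds, np.full(20, 0.05),
                                gap_open=2.0, gap_extend=0.5)
            # all short sequences exhaustively, longer ones sampled
            seqs = ["".join(p) for k in range(1, 4)
                    for p in itertools.product(alphabet4, repeat=k)]
            seqs += ["".join(rng.choice(list(alphabet4), size=k))
                     for k in (5, 6, 7, 8) for _ in range(10)]
            for seq in seqs:
                got, _ = score_sequence(prof, seq)
                expected = brute_force_glocal(prof, seq)
                assert got == pytest.approx(expected, abs=1e-9), (m, seq)
                n_checked += 1
        assert n_checked > 400

    def test_neutral_flanks_do_not_change_score(self):
        prof = build_profile(fam(["WWWWW"] * 4))
        inner = "WWWWW"
        s0, _ = score_sequence(prof, inner)
        s1, _ = score_sequence(prof, "ACDEFG" + inner + "GFEDCA")
        assert s1 == pytest.approx(s0)


class TestEvaluateSearch:
    def make_eval(self, threshold):
        msa, truth = generate_msa(MsaSpec(seed=8))
        block = msa.slice_columns(truth.motif_start, truth.motif_end + 1)
        prof = build_profile(block)
        db, dbt = generate_sequence_db(truth.consensus, n_positives=15,
                                       n_negatives=60, seed=8)
        return evaluate_search(prof, db, dbt.labels, threshold), prof, db, dbt

    def test_rate_arithmetic(self):
        # 8/10 members and 1/100 non-members score above threshold
        prof = build_profile(fam(["WWWWW"] * 3))
        hi, lo = "WWWWW", "AAAAA"
        sequences = {f"p{i}": (hi if i < 8 else lo) for i in range(10)}
        sequences.update({f"n{i}": (hi if i == 0 else lo) for i in range(100)})
        labels = {k: k.startswith("p") for k in sequences}
        s_hi, _ = score_sequence(prof, hi)
        s_lo, _ = score_sequence(prof, lo)
        ev = evaluate_search(prof, sequences, labels, (s_hi + s_lo) / 2)
        assert ev.tpr == pytest.approx(0.8)
        assert ev.fpr == pytest.approx(0.01)

    def test_threshold_minus_inf_gives_unit_rates(self):
        ev, *_ = self.make_eval(NEG_INF)
        assert ev.tpr == 1.0 and ev.fpr == 1.0

    def test_roc_monotone_in_threshold(self):
        ev_lo, prof, db, dbt = self.make_eval(-5.0)
        for thr in (0.0, 5.0, 10.0, 20.0):
            ev_hi = evaluate_search(prof, db, dbt.labels, thr)
            assert ev_hi.tpr <= ev_lo.tpr + 1e-12
            assert ev_hi.fpr <= ev_lo.fpr + 1e-12
            ev_lo = ev_hi

    def test_no_negatives_gives_none_fpr(self):
        msa, truth = generate_msa(MsaSpec(seed=8))
        block = msa.slice_columns(truth.motif_start, truth.motif_end + 1)
        prof = build_profile(block)
        db, dbt = generate_sequence_db(truth.consensus, n_positives=3,
                                       n_negatives=0, seed=1)
        ev = evaluate_search(prof, db, dbt.labels, 0.0)
        assert ev.fpr is None and ev.tpr is not None

    def test_exclusion_list_removes_false_positives(self):
        msa, truth = generate_msa(MsaSpec(seed=8))
        block = msa.slice_columns(truth.motif_start, truth.motif_end + 1)
        prof = build_profile(block)
        db, dbt = generate_sequence_db(truth.consensus, n_positives=5,
                                       n_negatives=20, seed=2)
        # mislabel one planted positive as a negative, then exclude it
        labels = dict(dbt.labels)
        labels["pos0001"] = False
        ev_raw = evaluate_search(prof, db, labels, 0.0)
        ev_corr = evaluate_search(prof, db, labels, 0.0, exclude={"pos0001"})
        assert ev_corr.fpr < ev_raw.fpr

    def test_missing_label_rejected(self):
        prof = build_profile(fam(["WWW"] * 2))
        with pytest.raises(GHMotifError):
            evaluate_search(prof, {"a": "WWW"}, {}, 0.0)


class TestGeneralization:
    def test_held_out_members_detected(self):
        """Profile from half the members generalizes to the other half."""
        msa, truth = generate_msa(MsaSpec(seed=13))
        block = msa.slice_columns(truth.motif_start, truth.motif_end + 1)
        half = AlignedFamily(
            "half", block.sequence_ids[:20], block.rows[:20],
            block.sequence_ids[0],
        )
        prof = build_profile(half)
        thr = calibrate_threshold(prof, seed=13, n_null=300)
        held_out_rows = block.rows[20:]
        flank = "ACDEFGHIKLMNPQRSTVWY"
        db = {f"h{i}": flank + row.replace("-", "") + flank
              for i, row in enumerate(held_out_rows)}
        rng = np.random.default_rng(13)
        db.update({
            f"n{i}": "".join(rng.choice(list(ALPHABET), size=55))
            for i in range(100)
        })
        labels = {k: k.startswith("h") for k in db}
        ev = evaluate_search(prof, db, labels, thr)
        assert ev.tpr >= 0.9
        assert ev.fpr <= 0.05
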