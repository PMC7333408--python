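"""Window extraction, consensus, Tm model, candidate enumeration and ranking."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hostblock.blocking_designer import (
    BlockingPrimer,
    CandidateScore,
    DesignConstraints,
    enumerate_candidates,
    extract_host_window,
    melting_temperature,
    modal_window,
    overlap_length,
    primer_pair_mean_tm,
    run_design,
    score_candidate,
    select_best,
    window_consensus,
)
from hostblock.insilico_pcr import (
    TABLE1_18SV4,
    TABLE1_BLOCKING_18SV4,
    Amplicon,
    PrimerSite,
    revcomp,
)
from hostblock.reference_db import ReferenceRecord, TaxonomyPath

REV = TABLE1_18SV4.reverse
dna = st.text(alphabet="ACGT", min_size=8, max_size=35)


def _amplicon(seq, rid="a1"):
    f = PrimerSite(rid, "+", 0, 20, 0)
    r = PrimerSite(rid, "-", len(seq) - 18, len(seq), 0)
    return Amplicon(rid, 0, len(seq), seq, f, r)


# ---------------------------------------------------------------- Tm model

# Independent oracle: SantaLucia & Hicks (2004) unified nearest-neighbor
# sum, hand-rolled from the published table.  kcal/mol (dH) and cal/mol/K
# (dS); duplex initiation 0.2/-5.7, terminal A:T penalty 2.2/6.9 per end;
# entropic salt correction 0.368*(N-1)*ln[Na+]; 250 nM single strand.
_NN = {
    "AA": (-7.6, -21.3), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = str.maketrans("ACGT", "TGCA")


def nn_tm_oracle(seq, na_molar=0.05, conc=250e-9):
    dh, ds = 0.2, -5.7
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.2
            ds += 6.9
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN:
            pair = pair.translate(_COMP)[::-1]
        h, s = _NN[pair]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    return 1000.0 * dh / (ds + 1.987 * math.log(conc)) - 273.15


class TestMeltingTemperature:
    @pytest.mark.parametrize(
        "seq",
        [
            "ACGTACGTACGTACGTACGT",
            TABLE1_BLOCKING_18SV4,
            "CCAGCACCTGCGGTAATTCC",
            "AATTAATTAATT",
            "GGGGCCCCGGGG",
        ],
    )
    def test_matches_independent_nn_sum(self, seq):
        assert melting_temperature(seq) == pytest.approx(nn_tm_oracle(seq), abs=1e-6)

    @given(dna)
    def test_agrees_with_oracle_on_random_oligos(self, seq):
        assert melting_temperature(seq) == pytest.approx(nn_tm_oracle(seq), abs=1e-6)

    @given(dna)
    def test_duplex_symmetry(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(revcomp(seq)), abs=1e-9
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            melting_temperature("ACGTACGTY")

    def test_pair_mean_averages_expansions(self):
        tm = primer_pair_mean_tm(TABLE1_18SV4)
        assert 45 < tm < 65


# ------------------------------------------------------- windows/consensus

class TestHostWindow:
    def test_window_is_terminal_slice(self):
        seq = "".join(random.Random(1).choice("ACGT") for _ in range(190))
        amp = _amplicon(seq)
        assert extract_host_window(amp, REV, 40) == seq[150:190]

    def test_window_equal_to_amplicon(self):
        seq = "A" * 40
        assert extract_host_window(_amplicon(seq), REV, 40) == seq

    def test_window_ends_with_reverse_site(self):
        rev_inst = REV.replace("Y", "T").replace("R", "A")
        seq = "ACGT" * 40 + revcomp(rev_inst)
        assert extract_host_window(_amplicon(seq), REV, 40).endswith(revcomp(rev_inst))

    def test_short_amplicon_rejected(self):
        with pytest.raises(ValueError):
            extract_host_window(_amplicon("A" * 39), REV, 40)


class TestConsensus:
    def test_single_window_is_itself(self):
        assert window_consensus(["ACGT"]) == "ACGT"

    def test_two_windows_use_iupac_codes(self):
        assert window_consensus(["ACGT", "ACTT"]) == "ACKT"

    def test_identical_windows_collapse(self):
        w = "TTAGTCAAGAACGAAAGTTAGG"
        assert window_consensus([w] * 50) == w

    def test_unequal_lengths_instruct_anchoring(self):
        with pytest.raises(ValueError, match="right-anchor"):
            window_consensus(["ACGT", "ACG"])

    def test_modal_window_majority(self):
        assert modal_window(["ACGT", "ACTT", "ACTT"]) == "ACTT"


# --------------------------------------------------------------- candidates

def host_window_with_planted_motif(pad=7):
    """Sense 3' window: pad | revcomp(blocker) minus overlap | host reverse
    site; the reverse-primer binding region sits at the extreme 3' end."""
    overlap = 10
    rev_variant = REV.replace("Y", "T").replace("R", "A")[:-overlap] + TABLE1_BLOCKING_18SV4[:overlap]
    window = (
        "GCGCGCA"[:pad]
        + revcomp(TABLE1_BLOCKING_18SV4)[: len(TABLE1_BLOCKING_18SV4) - overlap]
        + revcomp(rev_variant)
    )
    assert len(window) == pad + 15 + 18
    return window


class TestEnumerateCandidates:
    def test_constraints_hold_for_every_candidate(self):
        window = host_window_with_planted_motif()
        cands = enumerate_candidates(window, REV)
        assert cands
        for c in cands:
            assert len(c.sequence) < 30
            assert c.overlap_len == 10
            assert overlap_length(c.sequence, REV, 1) == 10

    def test_printed_blocking_primer_among_candidates(self):
        window = host_window_with_planted_motif()
        cands = enumerate_candidates(window, REV)
        assert TABLE1_BLOCKING_18SV4 in {c.sequence for c in cands}

    def test_single_length_constraint_gives_one_candidate(self):
        window = host_window_with_planted_motif()
        c = DesignConstraints(min_len=22, max_len=22, window_len=40)
        cands = enumerate_candidates(window, REV, c)
        assert len(cands) == 1 and len(cands[0].sequence) == 22

    def test_tm_filter_reports_not_drops(self):
        window = host_window_with_planted_motif()
        pair_tm = primer_pair_mean_tm(TABLE1_18SV4)
        cands = enumerate_candidates(window, REV, pair_tm=pair_tm)
        assert any(not c.within_tm_tolerance for c in cands)
        assert any(c.within_tm_tolerance for c in cands)


class TestOverlapLength:
    def test_printed_blocker_overlaps_ten_uniquely(self):
        assert overlap_length(TABLE1_BLOCKING_18SV4, REV, 1) == 10
        # exhaustive check that no longer prefix/suffix pair qualifies
        from hostblock.insilico_pcr import mismatch_count

        for k in range(11, len(REV) + 1):
            assert mismatch_count(TABLE1_BLOCKING_18SV4[:k], REV[-k:]) > 1

    def test_self_overlap_is_full_length(self):
        assert overlap_length(REV, REV, 0) == len(REV)

    def test_disjoint_sequences_overlap_zero(self):
        assert overlap_length("G" * 12, "A" * 12, 0) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_length("", REV)


# ------------------------------------------------------------------ scoring

def _recs(label, seqs):
    return [
        ReferenceRecord(f"{label}{i}", TaxonomyPath((label,)), s)
        for i, s in enumerate(seqs)
    ]


class TestScoreCandidate:
    def test_planted_in_all_targets_none_offtarget(self):
        cand = TABLE1_BLOCKING_18SV4
        rng = random.Random(2)
        targets = _recs(
            "host", ["".join(rng.choice("ACGT") for _ in range(50)) + revcomp(cand) for _ in range(20)]
        )
        off = _recs("prot", ["".join(rng.choice("ACGT") for _ in range(120)) for _ in range(50)])
        s = score_candidate(cand, targets, off, 0)
        assert (s.target_blocked_fraction, s.offtarget_blocked_fraction) == (1.0, 0.0)

    def test_absent_everywhere(self):
        targets = _recs("host", ["A" * 80] * 5)
        s = score_candidate("G" * 20, targets, targets, 0)
        assert (s.target_blocked_fraction, s.offtarget_blocked_fraction) == (0.0, 0.0)

    def test_empty_target_pool_rejected(self):
        with pytest.raises(ValueError, match="target"):
            score_candidate("ACGTACGTACGT", [], [], 0)


class TestSelectBest:
    def _cand(self, seq, tm_delta=0.0):
        return BlockingPrimer(seq, 10, 50.0, tm_delta)

    def test_single_candidate(self):
        pair = (self._cand("ACGTACGTACGTACGTAC"), CandidateScore(1.0, 0.0, 0.0))
        assert select_best([pair]) is pair[0]

    def test_offtarget_breaks_target_tie(self):
        a = (self._cand("AAAAAAAAAAAAAAAAAA"), CandidateScore(1.0, 0.0, 2.0))
        b = (self._cand("CCCCCCCCCCCCCCCCCC"), CandidateScore(1.0, 0.1, 0.0))
        assert select_best([a, b]) is a[0]

    def test_shorter_wins_through_full_tie(self):
        a = (self._cand("ACGTACGTACGTACGTACGTA"), CandidateScore(1.0, 0.0, 1.0))
        b = (self._cand("ACGTACGTACGTACGTACGT"), CandidateScore(1.0, 0.0, -1.0))
        assert select_best([a, b]) is b[0]

    def test_order_invariance(self):
        rng = random.Random(4)
        pool = [
            (
                self._cand("".join(rng.choice("ACGT") for _ in range(20)), rng.uniform(-3, 3)),
                CandidateScore(rng.choice([0.8, 1.0]), rng.choice([0.0, 0.1]), 0.0),
            )
            for _ in range(12)
        ]
        winners = set()
        for _ in range(10):
            rng.shuffle(pool)
            winners.add(select_best(pool).sequence)
        assert len(winners) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


# ------------------------------------------------------------- end to end

class TestRunDesign:
    def test_planted_motif_recovered_with_perfect_specificity(self, oyster_db, v4):
        records, _ = oyster_db
        res = run_design(records, v4, "Crassostrea")
        assert res.selected_score.target_blocked_fraction == 1.0
        assert res.selected_score.offtarget_blocked_fraction == 0.0
        assert TABLE1_BLOCKING_18SV4 in {c.sequence for c, _ in res.candidates}
        # selected primer satisfies every constraint post-hoc
        c = DesignConstraints()
        assert c.min_len <= len(res.selected.sequence) <= c.max_len
        assert len(res.selected.sequence) < 30
        assert res.selected.overlap_len == c.overlap_len
        assert abs(res.selected.tm_delta) <= c.tm_tolerance
        assert overlap_length(res.selected.sequence, v4.reverse, 1) == c.overlap_len

    def test_unknown_target_label_rejected(self, oyster_db, v4):
        records, _ = oyster_db
        with pytest.raises(ValueError, match="no records"):
            run_design(records, v4, "Vertebrata")
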