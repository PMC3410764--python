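"""Duplex scoring and candidate search, checked against brute-force oracles."""
from __future__ import annotations

import numpy as np
import pytest

from conftest import MIR160_SEQ, plant_site, random_dna, random_rna
from pareslice import duplex
from pareslice.duplex import (
    DEFAULT_SCHEME,
    PairState,
    PenaltyScheme,
    build_pairing,
    classify_pair,
    cleavage_site,
    find_candidate_sites,
    score_duplex,
)
from pareslice.models import MatureMiRNA, Transcript, revcomp_dna

# ---------------------------------------------------------------------------
# independent reference implementations (kept deliberately separate from the
# package: dict lookups, explicit loops, no shared helpers)

WC_PAIRS = {("A", "T"), ("C", "G"), ("G", "C"), ("U", "A")}
GU_PAIRS = {("G", "T"), ("U", "G")}


def ref_state(m: str, t: str) -> str:
    if (m, t) in WC_PAIRS:
        return "WC"
    if (m, t) in GU_PAIRS:
        return "GU"
    return "MM"


def ref_score(states, penalties=None) -> float:
    pen = penalties or {"WC": 0.0, "GU": 0.5, "MM": 1.0, "GAP": 1.0}
    total = 0.0
    for pos0, state in enumerate(states):
        weight = 2.0 if 2 <= pos0 + 1 <= 13 else 1.0
        total += weight * pen[state]
    return total


def ref_gapfree_sites(mirna_seq: str, transcript_seq: str, max_score: float):
    """Oracle: evaluate every gap-free window explicitly."""
    L = len(mirna_seq)
    out = []
    for e in range(L, len(transcript_seq) + 1):  # 1-based anchor of miRNA nt 1
        states = [ref_state(mirna_seq[i], transcript_seq[e - 1 - i]) for i in range(L)]
        score = ref_score(states)
        if score <= max_score and states[9] != "MM" and states[10] != "MM":
            out.append((e, score, e - 9))
    return out


# ---------------------------------------------------------------------------


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        mir = MIR160_SEQ
        pairing = [PairState.WC] * len(mir)
        assert score_duplex(mir, revcomp_dna(mir.replace("U", "T")), pairing) == 0.0

    def test_single_gu_outside_core(self):
        pairing = [PairState.WC] * 21
        pairing[19] = PairState.GU  # miRNA position 20
        assert score_duplex("A" * 21, "T" * 21, pairing) == pytest.approx(
            ref_score(["WC"] * 19 + ["GU", "WC"])
        )
        assert score_duplex("A" * 21, "T" * 21, pairing) == 0.5

    def test_single_mismatch_in_core_doubled(self):
        pairing = [PairState.WC] * 21
        pairing[4] = PairState.MM  # miRNA position 5, inside 2-13
        assert score_duplex("A" * 21, "T" * 21, pairing) == pytest.approx(
            ref_score(["WC"] * 4 + ["MM"] + ["WC"] * 16)
        )
        assert score_duplex("A" * 21, "T" * 21, pairing) == 2.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_duplex("ACGU", "ACGT", [PairState.WC] * 5)

    def test_order_independent_pure_sum(self, rng):
        states = list(rng.choice([PairState.WC, PairState.GU, PairState.MM], size=21))
        total = score_duplex("A" * 21, "T" * 21, states)
        ref = ref_score([s.value for s in states])
        assert total == pytest.approx(ref)

    def test_matches_reference_on_random_vectors(self, rng):
        for _ in range(50):
            states = list(
                rng.choice([PairState.WC, PairState.GU, PairState.MM], size=21)
            )
            assert score_duplex("A" * 21, "T" * 21, states) == pytest.approx(
                ref_score([s.value for s in states])
            )


class TestClassifyPair:
    @pytest.mark.parametrize(
        "m,t,state",
        [
            ("A", "T", PairState.WC),
            ("U", "A", PairState.WC),
            ("G", "C", PairState.WC),
            ("C", "G", PairState.WC),
            ("G", "T", PairState.GU),
            ("U", "G", PairState.GU),
            ("A", "A", PairState.MM),
            ("C", "T", PairState.MM),
            ("N", "A", PairState.MM),
        ],
    )
    def test_table(self, m, t, state):
        assert classify_pair(m, t) is state


class TestFindCandidateSites:
    def test_planted_perfect_site(self, mir160, planted_transcript):
        hits = find_candidate_sites(mir160, planted_transcript, max_score=7.0)
        perfect = [h for h in hits if h.score == 0.0]
        assert len(perfect) == 1
        hit = perfect[0]
        assert (hit.start, hit.end, hit.c_site) == (101, 121, 112)
        assert all(s is PairState.WC for s in hit.pairing)

    def test_score_above_threshold_excluded(self, rng, mir160):
        # a site scoring 7.5: one core mismatch (2), one core GU (1),
        # one outside mismatch (1), ... easier: rely on threshold sweep
        seq = plant_site(random_dna(rng, 200), mir160, end=121)
        tr = Transcript("t", seq)
        all_sites = {
            (h.end, round(h.score, 3)) for h in find_candidate_sites(mir160, tr, 100.0)
        }
        kept = {
            (h.end, round(h.score, 3)) for h in find_candidate_sites(mir160, tr, 7.0)
        }
        assert kept == {(e, s) for e, s in all_sites if s <= 7.0}
        assert any(s > 7.0 for _, s in all_sites)

    def test_mismatch_at_position10_excluded(self, rng, mir160):
        seq = plant_site(random_dna(rng, 200), mir160, end=121)
        # break the base pairing miRNA nt 10 (transcript position 112)
        partner = seq[111]
        for b in "ACGT":
            if ref_state(mir160.seq[9], b) == "MM":
                seq = seq[:111] + b + seq[112:]
                break
        assert seq[111] != partner
        tr = Transcript("t", seq)
        hits = find_candidate_sites(mir160, tr, max_score=7.0, allow_bulge=False)
        assert all(h.end != 121 for h in hits)
        # the rejected pairing would have scored well under the threshold
        states = [
            ref_state(mir160.seq[i], tr.seq[120 - i]) for i in range(len(mir160.seq))
        ]
        assert ref_score(states) <= 7.0

    def test_mismatch_at_position11_excluded(self, rng, mir160):
        seq = plant_site(random_dna(rng, 200), mir160, end=121)
        for b in "ACGT":
            if ref_state(mir160.seq[10], b) == "MM":
                seq = seq[:110] + b + seq[111:]
                break
        tr = Transcript("t", seq)
        hits = find_candidate_sites(mir160, tr, max_score=7.0, allow_bulge=False)
        assert all(h.end != 121 for h in hits)

    def test_gu_at_cleavage_site_allowed(self, rng):
        mir = MatureMiRNA("m", "A" * 9 + "G" + "A" * 11)  # position 10 is G
        site = revcomp_dna(mir.dna)  # ...C at the partner of nt 10
        e = 121
        seq = random_dna(rng, 200)
        start = e - len(site)
        seq = seq[:start] + site + seq[e:]
        partner_idx = e - 10  # 0-based transcript index pairing nt 10
        seq = seq[:partner_idx] + "T" + seq[partner_idx + 1 :]  # G:U wobble
        hits = find_candidate_sites(mir, Transcript("t", seq), max_score=7.0)
        match = [h for h in hits if h.end == e]
        assert match and match[0].pairing[9] is PairState.GU

    def test_short_transcript_warns_empty(self, mir160):
        with pytest.warns(UserWarning, match="shorter"):
            hits = find_candidate_sites(mir160, Transcript("t", "ACGT"), 7.0)
        assert hits == []

    def test_monotonicity_in_threshold(self, rng):
        mir = MatureMiRNA("m", random_rna(rng, 21))
        tr = Transcript("t", random_dna(rng, 500))
        previous: set = set()
        for threshold in (5.0, 8.0, 11.0, 14.0, 100.0):
            current = {
                (h.end, h.c_site) for h in find_candidate_sites(mir, tr, threshold)
            }
            assert previous <= current
            previous = current

    def test_gapfree_oracle_equivalence(self, rng):
        for rep in range(8):
            L = int(rng.integers(19, 23))
            mir = MatureMiRNA(f"m{rep}", random_rna(rng, L))
            tr = Transcript(f"t{rep}", random_dna(rng, int(rng.integers(60, 500))))
            for max_score in (7.0, 12.0):
                hits = find_candidate_sites(
                    mir, tr, max_score=max_score, allow_bulge=False
                )
                got = sorted((h.end, h.score, h.c_site) for h in hits)
                want = sorted(ref_gapfree_sites(mir.seq, tr.seq, max_score))
                assert got == want

    def test_csite_within_site_interval(self, rng):
        for rep in range(5):
            mir = MatureMiRNA(f"m{rep}", random_rna(rng, 21))
            tr = Transcript(f"t{rep}", random_dna(rng, 300))
            for h in find_candidate_sites(mir, tr, max_score=14.0):
                assert h.start <= h.c_site <= h.end

    def test_no_retained_site_breaks_the_gate(self, rng):
        for rep in range(5):
            mir = MatureMiRNA(f"m{rep}", random_rna(rng, 21))
            tr = Transcript(f"t{rep}", random_dna(rng, 300))
            for h in find_candidate_sites(mir, tr, max_score=100.0):
                assert h.pairing[9] in (PairState.WC, PairState.GU)
                assert h.pairing[10] in (PairState.WC, PairState.GU)


class TestGappedGeometry:
    def test_transcript_bulge_3prime_of_cleavage_keeps_csite(self, rng, mir160):
        # plant a perfect site, then insert one extra transcript base between
        # the partners of miRNA nt 5 and 6 (3' of the cleavage point)
        site = revcomp_dna(mir160.dna)
        prefix, suffix = random_dna(rng, 100), random_dna(rng, 100)
        bulged_site = site[:16] + "A" + site[16:]  # 16 = L - 5: between nt 5/6
        if ref_state(mir160.seq[4], "A") != "MM":
            bulged_site = site[:16] + "C" + site[16:]
        seq = prefix + bulged_site + suffix
        tr = Transcript("t", seq)
        gapfree_csite = 100 + len(site) - 9  # c_site measured from the site start
        hits = find_candidate_sites(mir160, tr, max_score=7.0)
        anchored = [h for h in hits if h.end == 100 + len(bulged_site)]
        assert anchored and anchored[0].config[0] == "tbulge"
        assert anchored[0].c_site == gapfree_csite
        assert cleavage_site(anchored[0]) == anchored[0].c_site

    def test_mirna_gap_pairing_map(self):
        # explicit geometry check on a crafted duplex
        mir = "ACGUACGUACGUACGUACGUA"
        tr_seq = "T" * 200
        states, partners, start = build_pairing(mir, tr_seq, end=150, config=("mgap", 3))
        assert partners[3] is None and states[3] is PairState.GAP
        assert partners[0] == 150 and partners[2] == 148
        assert partners[4] == 147  # one transcript base shared past the gap
        assert start == 150 - len(mir) + 2

    def test_tbulge_pairing_map(self):
        mir = "ACGUACGUACGUACGUACGUA"
        tr_seq = "T" * 200
        states, partners, start = build_pairing(mir, tr_seq, end=150, config=("tbulge", 3))
        assert partners[3] == 147 and partners[4] == 145  # 146 is the bulged base
        assert start == 150 - len(mir)
        assert len([p for p in partners if p is not None]) == len(mir)

    def test_gapfree_formula(self):
        mir = "ACGUACGUACGUACGUACGUA"
        states, partners, start = build_pairing(mir, "T" * 200, end=121, config=("free", None))
        assert partners[9] == 112  # e - 9
        assert start == 101

    def test_gap_never_between_positions_10_and_11(self):
        configs = duplex.enumerate_configs(21, allow_bulge=True)
        assert ("mgap", 9) not in configs and ("mgap", 10) not in configs
        assert ("tbulge", 9) not in configs

    def test_tie_prefers_gapfree(self, rng, mir160):
        seq = plant_site(random_dna(rng, 200), mir160, end=121)
        hits = find_candidate_sites(mir160, Transcript("t", seq), max_score=0.0)
        assert all(h.config == ("free", None) for h in hits)


class TestPenaltyConfig:
    def test_custom_scheme_changes_scores(self):
        pairing = [PairState.WC] * 21
        pairing[4] = PairState.MM
        hard = PenaltyScheme(mismatch=3.0)
        assert score_duplex("A" * 21, "T" * 21, pairing, hard) == 6.0

    def test_core_window_configurable(self):
        pairing = [PairState.WC] * 21
        pairing[4] = PairState.MM
        flat = PenaltyScheme(core_multiplier=1.0)
        assert score_duplex("A" * 21, "T" * 21, pairing, flat) == 1.0
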