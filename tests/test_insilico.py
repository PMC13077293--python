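"""Matching engine: window scoring, best-site scan, calls, amplicons.

The vectorized engine is cross-checked against the conftest brute-force
oracle (independent per-position set intersection over every placement).
"""

import numpy as np
import pytest

from cladeprimer import (
    FITS7,
    ITS3_CORALF,
    ITS4,
    ITS86F,
    MatchPolicy,
    Primer,
    SeqRecord,
    call_pair,
    call_single,
    extract_insert,
    reverse_complement,
    scan_template,
    window_mismatches,
)
from conftest import oracle_best, oracle_mask, oracle_summarize, random_iupac_seq


def _flanked(site: str, rng: np.random.Generator, flank: int = 25) -> SeqRecord:
    seq = random_iupac_seq(rng, flank) + site + random_iupac_seq(rng, flank)
    return SeqRecord(id="t", sequence=seq)


class TestWindowMismatches:
    def test_degenerate_primer_matches_realization(self, default_policy):
        mask, count, anchor_ok = window_mismatches(
            FITS7, "GTGAGTCATCGAATCTTTG", default_policy
        )
        assert count == 0 and anchor_ok and not any(mask)

    def test_single_internal_mismatch_position(self, default_policy):
        # ITS86F vs a template realizing the fITS7 site with R as G:
        # one mismatch at primer position 5 (1-based), outside the anchor
        mask, count, anchor_ok = window_mismatches(
            ITS86F, "GTGAGTCATCGAATCTTTGAA", default_policy
        )
        assert count == 1 and anchor_ok
        assert mask.index(True) == 4

    def test_terminal_substitution_breaks_anchor(self, default_policy):
        window = ITS3_CORALF.sequence[:-1] + "C"   # terminal A->C
        mask, count, anchor_ok = window_mismatches(ITS3_CORALF, window, default_policy)
        assert not anchor_ok and count == 0
        assert oracle_mask(ITS3_CORALF.sequence, window) == list(mask)

    def test_length_mismatch_rejected(self, default_policy):
        with pytest.raises(ValueError):
            window_mismatches(FITS7, "ACGT", default_policy)

    def test_strict_mode_penalizes_template_ambiguity(self):
        strict = MatchPolicy(template_ambiguity="strict")
        loose = MatchPolicy(template_ambiguity="intersection")
        window = "N" + "GTGAGTCATCGAATCTTTG"[1:]   # concrete realization, N at 1
        assert window_mismatches(FITS7, window, loose)[1] == 0
        assert window_mismatches(FITS7, window, strict)[1] == 1


class TestScanTemplate:
    def test_planted_exact_site_found(self, default_policy):
        rng = np.random.default_rng(11)
        flank = random_iupac_seq(rng, 17)
        rec = SeqRecord(id="t", sequence=flank + "GTGAGTCATCGAATCTTTG"
                        + random_iupac_seq(rng, 24))
        site = scan_template(FITS7, rec, default_policy)
        assert (site.start, site.mismatch_count, site.anchor_ok) == (17, 0, True)
        exp = oracle_best(FITS7.sequence, rec.sequence, 2)
        assert (site.start, site.mismatch_count) == exp[:2]

    def test_minimal_mismatch_site_wins(self, default_policy):
        rng = np.random.default_rng(5)
        primer = Primer("p", "ACGTACGTACGTACG", "forward")
        one_mm = "ACGTAGGTACGTACG"         # internal mismatch
        spacer = "TTTTTTTTTT"
        rec = SeqRecord(id="t", sequence=one_mm + spacer + primer.sequence)
        site = scan_template(primer, rec, default_policy)
        assert site.start == len(one_mm) + len(spacer)
        assert site.mismatch_count == 0

    def test_nonqualifying_best_returned_flagged(self, default_policy):
        primer = Primer("p", "AAAAAAAAAACCCCCCCCCC", "forward")
        rec = SeqRecord(id="t", sequence="GGGG" + "AATAATAAAACCCCTCCCCC" + "GGGG")
        site = scan_template(primer, rec, default_policy)
        assert site is not None and not site.qualifies(2)
        assert not call_single(primer, rec, default_policy).amplified

    def test_primer_longer_than_template(self, default_policy):
        rec = SeqRecord(id="t", sequence="ACGTACGT")
        assert scan_template(FITS7, rec, default_policy) is None
        call = call_single(FITS7, rec, default_policy)
        assert not call.amplified and call.best_site is None

    def test_reverse_primer_scans_revcomp_footprint(self, default_policy):
        rng = np.random.default_rng(23)
        rec = _flanked(reverse_complement(ITS4.sequence), rng)
        site = scan_template(ITS4, rec, default_policy)
        assert site.strand == "-" and site.mismatch_count == 0 and site.anchor_ok

    def test_reverse_primer_anchor_faces_insert(self, default_policy):
        # mutate the sense-strand base under the reverse primer's 3' end,
        # which is the *leftmost* footprint position
        rng = np.random.default_rng(29)
        foot = list(reverse_complement(ITS4.sequence))
        foot[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[foot[0]]
        rec = _flanked("".join(foot), rng)
        site = scan_template(ITS4, rec, default_policy)
        assert not site.anchor_ok


class TestOracleAgreement:
    def test_random_pairs_agree_with_enumeration(self):
        rng = np.random.default_rng(2024)
        policy = MatchPolicy()
        for _ in range(200):
            k = int(rng.integers(15, 26))
            n = int(rng.integers(60, 401))
            primer = Primer("p", random_iupac_seq(rng, k, ambig_rate=0.08), "forward")
            template = random_iupac_seq(rng, n, ambig_rate=0.03)
            rec = SeqRecord(id="t", sequence=template)
            site = scan_template(primer, rec, policy)
            exp = oracle_best(primer.sequence, template, policy.mismatch_budget)
            assert site.start == exp[0]
            assert site.mismatch_count == exp[1]
            assert site.anchor_ok == exp[2]
            assert site.qualifies(policy.mismatch_budget) == exp[3]
            assert list(site.mismatch_mask) == exp[4]


class TestProperties:
    def test_budget_monotonicity(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            primer = Primer("p", random_iupac_seq(rng, 18, 0.1), "forward")
            rec = SeqRecord(id="t", sequence=random_iupac_seq(rng, 120, 0.05))
            amplified = [
                call_single(primer, rec, MatchPolicy(mismatch_budget=b)).amplified
                for b in range(4)
            ]
            for a, b in zip(amplified, amplified[1:]):
                assert (not a) or b

    def test_degenerate_expansion_equivalence(self):
        # degenerate count at a window == min over concrete expansions
        from cladeprimer.seqcore import expansions
        rng = np.random.default_rng(37)
        policy = MatchPolicy()
        for _ in range(100):
            seq = list(random_iupac_seq(rng, 17))
            for pos in rng.choice(17, size=int(rng.integers(0, 4)), replace=False):
                seq[pos] = "RYSWKMBDHV"[rng.integers(0, 10)]
            primer = Primer("p", "".join(seq), "forward")
            window = random_iupac_seq(rng, 17)
            _, count, _ = window_mismatches(primer, window, policy)
            best = min(
                oracle_summarize(oracle_mask(e, window), 2)[0]
                for e in expansions(primer.sequence)
            )
            assert count == best

    def test_strand_symmetry(self):
        rng = np.random.default_rng(41)
        policy = MatchPolicy(scan_strand="both")
        for _ in range(25):
            primer = Primer("p", random_iupac_seq(rng, 18), "forward")
            site_seq = primer.sequence
            seq = random_iupac_seq(rng, 40) + site_seq + random_iupac_seq(rng, 40)
            rec = SeqRecord(id="t", sequence=seq)
            flipped = SeqRecord(id="t", sequence=reverse_complement(seq))
            a = scan_template(primer, rec, policy)
            b = scan_template(primer, flipped, policy)
            assert a.mismatch_count == b.mismatch_count == 0
            assert {a.strand, b.strand} == {"+", "-"}
            # coordinates map: start' = L - end
            assert b.start == len(seq) - a.end


class TestPairMode:
    @pytest.fixture()
    def pair_template(self):
        rng = np.random.default_rng(3)
        insert = random_iupac_seq(rng, 120)
        fl1, fl2 = random_iupac_seq(rng, 30), random_iupac_seq(rng, 30)
        seq = fl1 + "GTGAATCATCGAATCTTTG" + insert + \
            reverse_complement(ITS4.sequence) + fl2
        return SeqRecord(id="amp", sequence=seq), insert

    def test_amplicon_arithmetic(self, pair_template, default_policy):
        rec, insert = pair_template
        amp = call_pair(FITS7, ITS4, rec, default_policy)
        assert amp.length == 19 + 120 + 20 == 159
        assert amp.insert_length == 120
        assert extract_insert(amp, rec) == insert
        assert len(extract_insert(amp, rec, include_primers=True)) == 159

    def test_max_amplicon_cap(self, pair_template):
        rec, _ = pair_template
        tight = MatchPolicy(max_amplicon_len=150)
        assert call_pair(FITS7, ITS4, rec, tight) is None

    def test_reverse_anchor_mismatch_blocks_pair(self, default_policy):
        rng = np.random.default_rng(9)
        foot = list(reverse_complement(ITS4.sequence))
        foot[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[foot[0]]
        seq = (random_iupac_seq(rng, 30) + "GTGAATCATCGAATCTTTG"
               + random_iupac_seq(rng, 120) + "".join(foot)
               + random_iupac_seq(rng, 30))
        rec = SeqRecord(id="t", sequence=seq)
        assert call_pair(FITS7, ITS4, rec, default_policy) is None

    def test_role_mismatch_rejected(self, pair_template, default_policy):
        rec, _ = pair_template
        with pytest.raises(ValueError):
            call_pair(ITS4, ITS4, rec, default_policy)
        with pytest.raises(ValueError):
            call_pair(FITS7, FITS7, rec, default_policy)

    def test_zero_length_insert(self, default_policy):
        rng = np.random.default_rng(13)
        seq = (random_iupac_seq(rng, 25) + "GTGAATCATCGAATCTTTG"
               + reverse_complement(ITS4.sequence) + random_iupac_seq(rng, 25))
        rec = SeqRecord(id="t", sequence=seq)
        amp = call_pair(FITS7, ITS4, rec, default_policy)
        assert amp.insert_length == 0
        assert extract_insert(amp, rec) == ""
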