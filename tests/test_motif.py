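"""PWM construction and scanning against independent oracles.

Biopython's PSSM machinery serves as a second, independent scorer for
cross-checking; the package's own scanner never delegates to it.
"""

import itertools

import numpy as np
import pytest

from oracles import pwm_window_oracle
from tssoverlap.models import Pfm
from tssoverlap.motif import (
    DEFAULT_PSEUDOCOUNT,
    encode_sequence,
    pfm_to_pwm,
    reverse_complement,
    scan,
)


def random_pfm(rng, L, motif_id="M"):
    counts = rng.integers(0, 50, size=(4, L)).astype(float)
    counts[rng.integers(0, 4), :] += 5  # ensure positive columns
    return Pfm(motif_id, "TF", counts)


class TestPfmToPwm:
    def test_uniform_column_scores_zero(self):
        pfm = Pfm("M", "TF", np.full((4, 3), 10.0))
        pwm = pfm_to_pwm(pfm)
        np.testing.assert_allclose(pwm.matrix, 0.0, atol=1e-12)

    def test_dominant_base_positive_others_negative(self):
        counts = np.array([[97.0], [1.0], [1.0], [1.0]])
        pwm = pfm_to_pwm(Pfm("M", "TF", counts))
        assert pwm.matrix[0, 0] > 0
        assert (pwm.matrix[1:, 0] < 0).all()

    def test_matches_biopython_log_odds(self):
        """The conversion equals Biopython's normalize + log_odds with the
        background-split pseudocount."""
        from Bio import motifs as bio_motifs

        rng = np.random.default_rng(4)
        pfm = random_pfm(rng, 6)
        pwm = pfm_to_pwm(pfm)
        counts_dict = {b: list(pfm.counts[i]) for i, b in enumerate("ACGT")}
        m = bio_motifs.Motif(alphabet="ACGT", counts=bio_motifs.matrix.GenericPositionMatrix("ACGT", counts_dict))
        pssm = m.counts.normalize(pseudocounts=DEFAULT_PSEUDOCOUNT * 0.25).log_odds()
        expected = np.array([pssm[b] for b in "ACGT"])
        np.testing.assert_allclose(pwm.matrix, expected, atol=1e-10)

    @pytest.mark.parametrize("L", [1, 3, 6])
    def test_score_extrema_by_exhaustive_word_enumeration(self, L):
        rng = np.random.default_rng(L)
        pwm = pfm_to_pwm(random_pfm(rng, L))
        scores = [
            sum(pwm.matrix["ACGT".index(ch), j] for j, ch in enumerate(word))
            for word in ("".join(w) for w in itertools.product("ACGT", repeat=L))
        ]
        assert pwm.score_max == pytest.approx(max(scores))
        assert pwm.score_min == pytest.approx(min(scores))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            Pfm("M", "TF", np.empty((4, 0)))


class TestScan:
    def test_consensus_word_scores_relative_one(self):
        counts = np.zeros((4, 4))
        for j, b in enumerate("ACGT"):
            counts["ACGT".index(b), j] = 20
        counts += 0.5
        pwm = pfm_to_pwm(Pfm("M", "TF", counts))
        hits = scan("ACGT", pwm, rel_min=0.95, both_strands=False)
        assert len(hits) == 1 and hits[0].rel_score == pytest.approx(1.0)

    def test_rel_min_zero_reports_every_window_per_strand(self):
        rng = np.random.default_rng(6)
        pwm = pfm_to_pwm(random_pfm(rng, 5))
        seq = "".join(rng.choice(list("ACGT"), size=60))
        hits = scan(seq, pwm, rel_min=0.0)
        assert len(hits) == 2 * (60 - 5 + 1)

    def test_short_sequence_yields_nothing(self):
        pwm = pfm_to_pwm(random_pfm(np.random.default_rng(0), 8))
        assert scan("ACGT", pwm) == []

    def test_windows_containing_n_skipped(self):
        rng = np.random.default_rng(7)
        pwm = pfm_to_pwm(random_pfm(rng, 4))
        hits = scan("ACGNACGT", pwm, rel_min=0.0, both_strands=False)
        # windows 0..3 touch the N; only window 4 (ACGT) is scored
        assert [h.start for h in hits] == [4]

    def test_hit_set_matches_window_by_window_oracle(self):
        rng = np.random.default_rng(12)
        pwm = pfm_to_pwm(random_pfm(rng, 8))
        seq = "".join(rng.choice(list("ACGTN"), size=1000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        for rel_min in (0.0, 0.7, 0.95):
            hits = {(h.start, h.strand): h.raw_score
                    for h in scan(seq, pwm, rel_min=rel_min)}
            span = pwm.score_max - pwm.score_min
            fwd = pwm_window_oracle(seq, pwm.matrix)
            rc = pwm_window_oracle(reverse_complement(seq), pwm.matrix)
            expected = {}
            for i, s in enumerate(fwd):
                if s is not None and (s - pwm.score_min) / span >= rel_min:
                    expected[(i, "+")] = s
            n = len(seq) - 8 + 1
            for i, s in enumerate(rc):
                if s is not None and (s - pwm.score_min) / span >= rel_min:
                    expected[(n - 1 - i, "-")] = s  # mirror onto forward coordinates
            assert set(hits) == set(expected)
            for k in expected:
                assert hits[k] == pytest.approx(expected[k], abs=1e-9)

    def test_reverse_complement_symmetry(self):
        """Scanning the reverse complement yields the strand-swapped,
        coordinate-mirrored hit set."""
        rng = np.random.default_rng(13)
        pwm = pfm_to_pwm(random_pfm(rng, 6))
        seq = "".join(rng.choice(list("ACGT"), size=300))
        fwd_hits = scan(seq, pwm, rel_min=0.5)
        rc_hits = scan(reverse_complement(seq), pwm, rel_min=0.5)
        n = len(seq) - 6 + 1
        mirrored = {(n - 1 - h.start, {"+": "-", "-": "+"}[h.strand]) for h in rc_hits}
        assert {(h.start, h.strand) for h in fwd_hits} == mirrored

    def test_rel_scores_always_in_unit_interval(self):
        rng = np.random.default_rng(14)
        pwm = pfm_to_pwm(random_pfm(rng, 5))
        seq = "".join(rng.choice(list("ACGT"), size=200))
        for h in scan(seq, pwm, rel_min=0.0):
            assert 0.0 <= h.rel_score <= 1.0 + 1e-12

    def test_matches_biopython_pssm_scores(self):
        """Independent cross-check: Biopython's PSSM.calculate agrees with
        the package scanner on forward-strand raw scores."""
        from Bio import motifs as bio_motifs
        from Bio.Seq import Seq

        rng = np.random.default_rng(15)
        pfm = random_pfm(rng, 7)
        pwm = pfm_to_pwm(pfm)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        counts_dict = {b: list(pfm.counts[i]) for i, b in enumerate("ACGT")}
        m = bio_motifs.Motif(alphabet="ACGT", counts=bio_motifs.matrix.GenericPositionMatrix("ACGT", counts_dict))
        pssm = m.counts.normalize(pseudocounts=DEFAULT_PSEUDOCOUNT * 0.25).log_odds()
        bio_scores = pssm.calculate(Seq(seq))
        ours = {h.start: h.raw_score for h in scan(seq, pwm, rel_min=0.0, both_strands=False)}
        np.testing.assert_allclose(
            [ours[i] for i in range(len(bio_scores))], np.asarray(bio_scores), atol=1e-4
        )

    def test_encode_sequence_maps_unknowns_to_minus_one(self):
        np.testing.assert_array_equal(encode_sequence("ACGTNX"), [0, 1, 2, 3, -1, -1])
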