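"""Codon alignment, translation and premature-termination typing."""

import numpy as np
import pytest
from Bio.Seq import Seq

from notchevo.errors import ValidationError
from notchevo.synthetic import MECHANISM_CHOICES, plant_truncation, random_cds
from notchevo.truncation import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH,
    MISMATCH,
    align_cds,
    classify_mechanism,
    edits_from_alignment,
    termination_window_check,
    translate,
)
from notchevo.config import RunConfig

from conftest import paralog_pair


class TestTranslate:
    @pytest.mark.parametrize(
        "cds, protein, stop",
        [
            ("ATGAAATAA", "MK", 3),
            ("ATGTGA", "M", 2),
            ("ATGCTGACCTAA", "MLT", 4),
            ("ATGNNNTAA", "MX", 3),
            ("TANAA", "X", None),  # N codon is X, never a stop; tail ignored
        ],
    )
    def test_standard_code_examples(self, cds, protein, stop):
        assert translate(cds) == (protein, stop)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            translate("AT")

    def test_agrees_with_biopython_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(2, 60))
            cds = "".join(rng.choice(list("ACGT"), size=3 * n))
            mine, _ = translate(cds)
            oracle = str(Seq(cds).translate(to_stop=True))
            assert mine == oracle


def plain_affine_dp(a: str, b: str) -> float:
    """Independent scalar Gotoh scorer used as the optimum oracle."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    D = [[neg] * (m + 1) for _ in range(n + 1)]
    I = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = -GAP_OPEN - (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        I[0][j] = -GAP_OPEN - (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1]) + s
            D[i][j] = max(M[i - 1][j] - GAP_OPEN, D[i - 1][j] - GAP_EXTEND,
                          I[i - 1][j] - GAP_OPEN)
            I[i][j] = max(M[i][j - 1] - GAP_OPEN, D[i][j - 1] - GAP_OPEN,
                          I[i][j - 1] - GAP_EXTEND)
    return max(M[n][m], D[n][m], I[n][m])


def alignment_score(aln) -> float:
    """Re-score an alignment from its columns (independent of the DP)."""
    score, prev_gap = 0.0, None
    for x, y in zip(aln.ref_aln, aln.alt_aln):
        if x == "-" or y == "-":
            which = "r" if x == "-" else "a"
            score -= GAP_EXTEND if prev_gap == which else GAP_OPEN
            prev_gap = which
        else:
            score += MATCH if x == y else MISMATCH
            prev_gap = None
    return score


class TestAlignment:
    def test_identical_sequences_align_gap_free(self):
        aln = align_cds("ATGCTGACCTAA", "ATGCTGACCTAA")
        assert set(aln.columns) == {"match"}

    def test_single_deletion_yields_one_gap_column(self):
        aln = align_cds("ATGCTGACCTAA", "ATGTGACCTAA")
        assert aln.columns.count("deletion_in_alt") == 1
        assert aln.columns.count("insertion_in_alt") == 0

    def test_single_substitution_yields_no_gaps(self):
        aln = align_cds("ATGCTGACCTAA", "ATGCTCACCTAA")
        assert aln.columns.count("substitution") == 1
        assert "-" not in aln.ref_aln + aln.alt_aln

    def test_score_equals_independent_dp_optimum(self):
        rng = np.random.default_rng(5)
        for _ in range(12):
            n = int(rng.integers(10, 60))
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = list(a)
            for _ in range(int(rng.integers(1, 5))):  # a few random edits
                op = rng.integers(3)
                pos = int(rng.integers(len(b)))
                if op == 0:
                    b[pos] = str(rng.choice(list("ACGT")))
                elif op == 1 and len(b) > 5:
                    del b[pos]
                else:
                    b.insert(pos, str(rng.choice(list("ACGT"))))
            b = "".join(b)
            aln = align_cds(a, b)
            assert aln.score == plain_affine_dp(a, b)
            # the emitted alignment must actually achieve the optimum
            assert alignment_score(aln) == aln.score

    def test_degapped_rows_reproduce_inputs(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=40))
            b = "".join(rng.choice(list("ACGT"), size=38))
            aln = align_cds(a, b)
            assert aln.degapped() == (a, b)

    def test_homopolymer_gap_is_left_normalised(self):
        # deleting any A of the run is equivalent; canonical placement is
        # the run's first base
        aln = align_cds("CCAAAACC", "CCAAACC")
        gap_col = aln.alt_aln.index("-")
        assert aln.ref_aln[gap_col] == "A"
        assert gap_col == 2

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            align_cds("", "ATG")


class TestClassifyMechanism:
    def test_single_base_deletion_worked_example(self):
        # ATG CTG ACC TAA with the 4th base deleted: reading becomes
        # ATG TGA ... -> stop at codon 2 through a frameshift
        report = classify_mechanism(paralog_pair("ATGCTGACCTAA", "ATGTGACCTAA"))
        assert report.premature
        assert report.alt_stop_codon_index == 2
        assert report.mechanism == "deletion_frameshift"

    def test_tta_to_tga_mid_base_substitution(self):
        ref = "ATG" + "CTG" * 3 + "TTA" + "GCT" * 3 + "TAA"
        alt = ref[:13] + "G" + ref[14:]  # TTA -> TGA at codon 5
        report = classify_mechanism(paralog_pair(ref, alt))
        assert report.mechanism == "substitution_nonsense"
        assert report.alt_stop_codon_index == 5

    def test_identical_pair_reports_none(self):
        cds = random_cds(40, seed=3)
        report = classify_mechanism(paralog_pair(cds, cds))
        assert not report.premature and report.mechanism == "none"

    @pytest.mark.parametrize("mechanism", MECHANISM_CHOICES)
    def test_planted_mechanism_and_coordinate_recovered(self, mechanism):
        recovered = 0
        target = 0
        seed = 0
        while recovered < 10 and seed < 300:
            seed += 1
            ref = random_cds(90, seed=seed)
            try:
                alt, truth = plant_truncation(ref, mechanism, 30, seed=seed)
            except Exception:
                continue
            report = classify_mechanism(paralog_pair(ref, alt))
            assert report.mechanism == mechanism
            assert report.causal_edit.alt_pos == truth.payload["alt_pos"]
            assert report.alt_stop_codon_index == truth.payload["stop_codon"]
            recovered += 1
        assert recovered == 10


class TestTerminationWindow:
    def _report_with_offset(self, offset):
        # anchor R followed by `offset` codons then the planted stop
        pre = "CGT" + "GCT" * (offset - 1)  # R then offset-1 sense codons
        ref = "ATG" + "GAA" * 5 + pre + "TTA" + "GCT" * 20 + "TAA"
        stop_codon0 = 3 * (6 + offset)  # 0-based nt of the TTA codon
        alt = ref[: stop_codon0 + 1] + "G" + ref[stop_codon0 + 2 :]  # TTA->TGA
        return classify_mechanism(paralog_pair(ref, alt))

    def test_offset_five_is_within_window(self):
        report = self._report_with_offset(5)
        assert report.anchor_offset == 5
        assert termination_window_check(report) is True

    def test_offset_thirty_is_outside_window(self):
        report = self._report_with_offset(30)
        assert report.anchor_offset == 30
        assert termination_window_check(report) is False

    def test_no_anchor_is_indeterminate_not_false(self):
        ref = "ATG" + "GCT" * 10 + "TTA" + "GCT" * 5 + "TAA"  # no R anywhere
        alt = ref[: 3 * 11 + 1] + "G" + ref[3 * 11 + 2 :]
        report = classify_mechanism(paralog_pair(ref, alt))
        assert report.anchor_offset is None
        assert termination_window_check(report) is None

    def test_window_bounds_come_from_config(self):
        report = self._report_with_offset(5)
        tight = RunConfig(window_lo=1, window_hi=3)
        assert termination_window_check(report, tight) is False
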