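import math

import numpy as np
import pytest

from expertpe.amplicon_quant import (
    QuantResult,
    align_global,
    classify_read,
    fold_change,
    quant_spec_from_design,
    quantify,
)
from expertpe.synthetic_fixtures import read_recipe_for_design, simulate_reads

BASES = "ACGT"


def enumerate_best_score(a, b, match=1, mismatch=-1, gap=-2):
    """Independent oracle: exhaustively enumerate all global alignments."""
    best = -(10**9)

    def rec(i, j, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            rec(i + 1, j, score + gap)
        if j < len(b):
            rec(i, j + 1, score + gap)

    rec(0, 0, 0)
    return best


class TestAlignGlobal:
    def test_identical(self):
        aln = align_global("ACGT", "ACGT")
        assert aln.score == 4 and "-" not in aln.aligned_a + aln.aligned_b

    def test_single_gap(self):
        assert align_global("ACGT", "AGT").score == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT")

    @pytest.mark.parametrize("seed", range(30))
    def test_score_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(BASES[i] for i in rng.integers(4, size=rng.integers(1, 30)))
        b = "".join(BASES[i] for i in rng.integers(4, size=rng.integers(1, 30)))
        assert align_global(a, b).score == align_global(b, a).score

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_enumeration_oracle_small(self, seed):
        rng = np.random.default_rng(1000 + seed)
        a = "".join(BASES[i] for i in rng.integers(4, size=rng.integers(1, 9)))
        b = "".join(BASES[i] for i in rng.integers(4, size=rng.integers(1, 9)))
        assert align_global(a, b).score == enumerate_best_score(a, b)

    def test_matches_biopython_on_longer_pairs(self):
        """Independent cross-check against Bio.Align under the same scheme."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = "".join(BASES[i] for i in rng.integers(4, size=rng.integers(10, 80)))
            b = "".join(BASES[i] for i in rng.integers(4, size=rng.integers(10, 80)))
            assert align_global(a, b).score == aligner.score(a, b)


@pytest.fixture(scope="module")
def quant_setup(top_design):
    d, frame = top_design
    return d, frame, quant_spec_from_design(frame, d)


class TestClassifyRead:
    def test_exact_edited_is_intended(self, quant_setup):
        _, _, spec = quant_setup
        assert classify_read(spec.edited_allele, spec) == "intended"

    def test_exact_ref_is_unedited(self, quant_setup):
        _, _, spec = quant_setup
        assert classify_read(spec.ref_allele, spec) == "unedited"

    def test_deletion_at_ext_nick_is_indel(self, quant_setup):
        d, _, spec = quant_setup
        x = d.pair.ext.nick
        read = spec.ref_allele[:x] + spec.ref_allele[x + 1 :]
        assert classify_read(read, spec) == "indel"

    def test_insertion_at_ups_nick_is_indel(self, quant_setup):
        d, _, spec = quant_setup
        u = d.pair.ups.nick
        read = spec.ref_allele[:u] + "ACACA" + spec.ref_allele[u:]
        assert classify_read(read, spec) == "indel"

    def test_payload_change_on_edited_read_is_substituted(self, quant_setup):
        d, _, spec = quant_setup
        p = min(spec.ed_check_positions)
        base = spec.edited_allele[p]
        new = "C" if base != "C" else "G"
        read = spec.edited_allele[:p] + new + spec.edited_allele[p + 1 :]
        assert classify_read(read, spec) == "substituted"

    def test_short_fragment_is_unassigned(self, quant_setup):
        _, _, spec = quant_setup
        span = spec.ed_window[1] - spec.ed_window[0]
        read = spec.edited_allele[: span - 5]  # shorter than the window span
        assert classify_read(read, spec) == "unassigned"

    def test_error_outside_edit_region_still_intended(self, quant_setup):
        _, _, spec = quant_setup
        read = "A" + spec.edited_allele[1:]
        if read == spec.edited_allele:
            read = "C" + spec.edited_allele[1:]
        assert classify_read(read, spec) == "intended"


class TestQuantify:
    def test_counting_example(self, quant_setup):
        d, _, spec = quant_setup
        x = d.pair.ext.nick
        deleted = spec.ref_allele[:x] + spec.ref_allele[x + 1 :]
        reads = [spec.edited_allele] * 40 + [deleted] * 5 + [spec.ref_allele] * 55
        res = quantify(reads, spec)
        assert res.efficiency == 40.0
        assert res.indel_rate == 5.0
        assert res.purity == 8.0
        assert res.n_unedited == 55

    def test_all_edited_gives_infinite_purity(self, quant_setup):
        _, _, spec = quant_setup
        res = quantify([spec.edited_allele] * 10, spec)
        assert res.efficiency == 100.0 and res.indel_rate == 0.0
        assert math.isinf(res.purity)
        assert res.to_dict()["purity"] == "inf"

    def test_count_conservation_enforced(self):
        with pytest.raises(ValueError):
            QuantResult(10, 5, 1, 1, 1, 1)

    def test_empty_reads_rejected(self, quant_setup):
        _, _, spec = quant_setup
        with pytest.raises(ValueError):
            quantify([], spec)

    def test_recovers_planted_fractions_exactly(self, top_design):
        d, frame = top_design
        spec = quant_spec_from_design(frame, d)
        recipe = read_recipe_for_design(
            d, frame, seed=5, n_reads=200,
            f_intended=0.25, f_indel=0.10, f_unedited=0.60,
        )
        reads = [s for _, s in simulate_reads(spec.ref_allele, spec.edited_allele, recipe)]
        res = quantify(reads, spec)
        assert (res.n_intended, res.n_indel, res.n_unedited, res.n_substituted) == (
            50, 20, 120, 10,
        )


class TestFoldChange:
    @pytest.mark.parametrize(
        "treat,ctrl,digits,expected",
        [
            (9.13, 0.23, 1, 39.7),
            (3.22, 0.07, 0, 46.0),
            (6.86, 1.13, 1, 6.1),
            (3.1, 0.21, 0, 15.0),
            (5.0, 5.0, 1, 1.0),
        ],
    )
    def test_printed_pairs(self, treat, ctrl, digits, expected):
        assert fold_change(treat, ctrl, digits) == expected

    def test_purity_from_printed_efficiency_and_indel(self):
        """Intended 33.7% over indels 0.52% gives product purity 64.8."""
        assert fold_change(33.7, 0.52, 1) == 64.8

    def test_zero_control_marker(self):
        assert math.isinf(fold_change(1.0, 0.0))

    def test_rounding_is_half_up(self):
        assert fold_change(1.25, 1.0, 1) == 1.3
        assert fold_change(0.15, 1.0, 1) == 0.2
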