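import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from expertpe.config import DEFAULT_SCAFFOLD
from expertpe.construct_builder import (
    MISMATCH_MAP,
    DesignWarning,
    MismatchInfeasibleError,
    assemble_ext_pegrna,
    build_es,
    build_hs,
    build_pbs,
    build_sgrna,
    decode_ext_pegrna,
    es_end_for,
    introduce_mismatches,
    retained_flanks,
)
from expertpe.sequence_core import EditAtom, EditSpec, Locus, apply_edit, revcomp

BASES = np.array(list("ACGT"))


def random_locus(rng, n=300, name="r"):
    return Locus(name, "".join(BASES[rng.integers(4, size=n)]))


class TestBuildPbs:
    def test_poly_a_example(self):
        locus = Locus("t", "AAAAAAAAAAAG" + "C" * 20)
        assert build_pbs(locus, 12, 12) == "CTTTTTTTTTTT"

    def test_matches_revcomp_oracle(self):
        locus = Locus("t", "ACGGCTAGCTAA" + "C" * 20)
        assert build_pbs(locus, 12, 12) == revcomp("ACGGCTAGCTAA")

    def test_default_silent_short_warns(self):
        locus = random_locus(np.random.default_rng(1))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            build_pbs(locus, 50, 12)  # recommended length: no warning
        with pytest.warns(DesignWarning, match="9"):
            build_pbs(locus, 50, 8)

    def test_bounds(self):
        locus = random_locus(np.random.default_rng(2))
        with pytest.raises(ValueError):
            build_pbs(locus, 5, 12)
        with pytest.raises(ValueError):
            build_pbs(locus, 50, 0)


class TestBuildEs:
    def test_full_internick_deletion_gives_empty_es(self):
        locus = random_locus(np.random.default_rng(3))
        edit = EditSpec(atoms=(EditAtom(100, 137, ""),))
        assert build_es(locus, edit, 100, 137) == ""

    def test_full_window_replacement_is_payload_verbatim(self):
        locus = random_locus(np.random.default_rng(4))
        payload = "".join(BASES[np.random.default_rng(5).integers(4, size=37)])
        edit = EditSpec(atoms=(EditAtom(100, 137, payload),))
        assert build_es(locus, edit, 100, 137) == payload

    def test_interior_replacement_equals_product_slice(self):
        """ES must equal the product of independent string surgery."""
        locus = random_locus(np.random.default_rng(6))
        u, x = 100, 137
        edit = EditSpec(atoms=(EditAtom(u + 5, u + 8, "T"),))
        es = build_es(locus, edit, u, x)
        assert len(es) == 35
        product = apply_edit(locus, edit)
        assert es == product[u : u + 35]

    def test_upstream_atom_rejected(self):
        locus = random_locus(np.random.default_rng(7))
        edit = EditSpec(atoms=(EditAtom(90, 95, ""),))
        with pytest.raises(Exception, match="upstream"):
            build_es(locus, edit, 100, 137)


class TestBuildHs:
    def test_literal_slice(self):
        locus = random_locus(np.random.default_rng(8))
        assert build_hs(locus, 100, 16) == locus.sequence[100:116]

    def test_hs12_warns_hs22_silent(self):
        locus = random_locus(np.random.default_rng(9))
        with pytest.warns(DesignWarning, match="16"):
            build_hs(locus, 100, 12)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            build_hs(locus, 100, 22)

    def test_bounds_error(self):
        locus = random_locus(np.random.default_rng(10))
        with pytest.raises(ValueError):
            build_hs(locus, 290, 16)


def deletion_with_3p_flank(u=100, x=137, flank=17):
    """Deletion leaving `flank` retained nt adjacent to the ext nick."""
    return EditSpec(atoms=(EditAtom(u, x - flank, ""),))


class TestMismatches:
    def test_consecutive_11_abuts_ext_nick(self):
        rng = np.random.default_rng(11)
        locus = random_locus(rng)
        u, x = 100, 137
        edit = deletion_with_3p_flank(u, x, 17)
        es = build_es(locus, edit, u, x)
        es_mm, plan = introduce_mismatches(es, edit, u, x, "consecutive", 11)
        diffs = [i for i, (a, b) in enumerate(zip(es, es_mm)) if a != b]
        assert len(diffs) == 11
        assert diffs == list(range(len(es) - 11, len(es)))  # contiguous, nick-adjacent
        assert plan.positions == tuple(range(x - 11, x))
        assert all(es_mm[i] == MISMATCH_MAP[es[i]] for i in diffs)

    def test_none_scheme_is_identity(self):
        rng = np.random.default_rng(12)
        locus = random_locus(rng)
        edit = deletion_with_3p_flank()
        es = build_es(locus, edit, 100, 137)
        es_mm, plan = introduce_mismatches(es, edit, 100, 137, "none", 0)
        assert es_mm == es and plan.count == 0

    def test_every3_offsets(self):
        """15-nt flank, every-3rd-base scheme, k=5: offsets 0,3,6,9,12."""
        rng = np.random.default_rng(13)
        locus = random_locus(rng)
        u, x = 100, 137
        edit = EditSpec(atoms=(EditAtom(u, x - 15, ""),))
        es = build_es(locus, edit, u, x)
        es_mm, plan = introduce_mismatches(es, edit, u, x, "every3", 5)
        offsets = sorted((x - 1) - p for p in plan.positions)
        assert offsets == [0, 3, 6, 9, 12]

    def test_every5_offsets(self):
        rng = np.random.default_rng(14)
        locus = random_locus(rng)
        u, x = 100, 151
        edit = EditSpec(atoms=(EditAtom(u, x - 21, ""),))
        es = build_es(locus, edit, u, x)
        es_mm, plan = introduce_mismatches(es, edit, u, x, "every5", 4)
        offsets = sorted((x - 1) - p for p in plan.positions)
        assert offsets == [0, 5, 10, 15]

    def test_infeasible_reports_max_k(self):
        rng = np.random.default_rng(15)
        locus = random_locus(rng)
        edit = deletion_with_3p_flank(100, 137, 5)
        es = build_es(locus, edit, 100, 137)
        with pytest.raises(MismatchInfeasibleError, match="max feasible k=5"):
            introduce_mismatches(es, edit, 100, 137, "consecutive", 11)

    def test_five_prime_side_starts_at_ups_nick(self):
        rng = np.random.default_rng(16)
        locus = random_locus(rng)
        u, x = 100, 137
        edit = EditSpec(atoms=(EditAtom(u + 20, x, "ACA"),))  # retained 5' flank of 20
        es = build_es(locus, edit, u, x)
        es_mm, plan = introduce_mismatches(
            es, edit, u, x, "consecutive", 11, side="five_prime_flap"
        )
        assert plan.positions == tuple(range(u, u + 11))
        assert es_mm[:11] != es[:11] and es_mm[11:] == es[11:]

    @pytest.mark.parametrize("k", range(0, 18))
    def test_hamming_distance_equals_k(self, k):
        """Mismatch-count conservation across the full tested sweep 0..17."""
        rng = np.random.default_rng(17)
        locus = random_locus(rng)
        u, x = 100, 137
        edit = deletion_with_3p_flank(u, x, 17)
        es = build_es(locus, edit, u, x)
        es_mm, plan = introduce_mismatches(es, edit, u, x, "consecutive", k)
        assert sum(a != b for a, b in zip(es, es_mm)) == k
        assert plan.count == k

    def test_retained_flanks_insertion_breaks_run(self):
        u, x = 100, 137
        edit = EditSpec(atoms=(EditAtom(120, 120, "AAA"),))
        (f5s, f5e), (f3s, f3e) = retained_flanks(edit, u, x)
        assert (f5s, f5e) == (100, 120)
        assert (f3s, f3e) == (120, 137)


class TestAssembly:
    def _components(self, seed):
        rng = np.random.default_rng(seed)
        spacer = "".join(BASES[rng.integers(4, size=20)])
        es = "".join(BASES[rng.integers(4, size=int(rng.integers(0, 60)))])
        hs = "".join(BASES[rng.integers(4, size=16)])
        pbs = "".join(BASES[rng.integers(4, size=12)])
        return spacer, es, hs, pbs

    def test_layout_and_length_additivity(self):
        spacer, es, hs, pbs = self._components(18)
        peg = assemble_ext_pegrna(spacer, DEFAULT_SCAFFOLD, es, hs, pbs)
        assert len(peg.full) == 20 + len(DEFAULT_SCAFFOLD) + len(es) + len(hs) + len(pbs)
        assert peg.full == spacer + DEFAULT_SCAFFOLD + revcomp(hs) + revcomp(es) + pbs
        assert revcomp(peg.rtt) == es + hs

    def test_empty_es_extension_is_rc_hs_plus_pbs(self):
        spacer, _, hs, pbs = self._components(19)
        peg = assemble_ext_pegrna(spacer, DEFAULT_SCAFFOLD, "", hs, pbs)
        assert peg.extension == revcomp(hs) + pbs

    def test_empty_spacer_or_scaffold_rejected(self):
        with pytest.raises(ValueError):
            assemble_ext_pegrna("", DEFAULT_SCAFFOLD, "A", "C", "G")
        with pytest.raises(ValueError):
            assemble_ext_pegrna("A" * 20, "", "A", "C", "G")

    @pytest.mark.parametrize("seed", range(40))
    def test_roundtrip_decoding(self, seed):
        """Decoding full with the known scaffold recovers all components."""
        spacer, es, hs, pbs = self._components(seed)
        peg = assemble_ext_pegrna(spacer, DEFAULT_SCAFFOLD, es, hs, pbs)
        assert decode_ext_pegrna(
            peg.full, DEFAULT_SCAFFOLD, len(es), len(hs), len(pbs)
        ) == (spacer, es, hs, pbs)


class TestSgrna:
    @pytest.mark.parametrize(
        "spacer,u6,expected_prefix",
        [("G" + "A" * 19, True, "G" + "A" * 19), ("A" * 20, True, "G" + "A" * 20),
         ("A" * 20, False, "A" * 20)],
    )
    def test_u6_prefix(self, spacer, u6, expected_prefix):
        out = build_sgrna(spacer, DEFAULT_SCAFFOLD, u6_g=u6)
        assert out == expected_prefix + DEFAULT_SCAFFOLD
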