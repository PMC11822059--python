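"""Assembly of the ext-pegRNA, ups-sgRNA and Helper gRNA constructs.

The ext-pegRNA is ``spacer + scaffold + 3' extension`` where the
extension is an RT template (RTT) followed by a primer binding site
(PBS).  The RTT consists of an edit sequence (ES) covering the
product from the ups nick through the last edited base, and a
homologous sequence (HS) that is genome-identical downstream of the
edit and mediates flap annealing.  ES and HS are stored here in
synthesized-strand (product) orientation; the encoded construct
carries their reverse complements, RTT 5' of the PBS, because reverse
transcription reads the extension 3'->5' starting at the PBS junction.

When the editing region sits >= ~14 nt away from a nick, the genomic
flap released by that nick can re-hybridize with the complementary
stretch of the extension and stall the reverse transcriptase.
Deliberate mismatches in the retained (genome-identical) part of the
ES disrupt this hybridization; 10-11 consecutive mismatches starting
at the nick-adjacent flap terminus are optimal, with every-3rd/every-
5th-base spacings as alternatives.  The mismatches are real product
changes and are carried into the predicted allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .guide_search import GuidePair
from .sequence_core import (
    EditAtom,
    EditError,
    EditSpec,
    Locus,
    _check_dna,
    apply_edit_window,
    revcomp,
)

PBS_DEFAULT = 12
PBS_RANGE = (9, 16)
HS_DEFAULT = 16
HS_TESTED_MIN = 12
MISMATCH_K_DEFAULT = 11

#: Fixed transversion substitution map used for mismatch introduction
#: (deterministic and maximally destabilizing for the flap duplex).
MISMATCH_MAP = {"A": "C", "C": "A", "G": "T", "T": "G"}

MISMATCH_SPACING = {"consecutive": 1, "every3": 3, "every5": 5}


class DesignWarning(UserWarning):
    """Parameter outside the empirically recommended range."""


class MismatchInfeasibleError(ValueError):
    """Retained flank too short for the requested mismatch scheme."""


@dataclass(frozen=True)
class MismatchPlan:
    """Where and how the ES was deliberately mismatched.

    ``positions`` are absolute working-strand (reference) indices of
    retained bases whose product copy was substituted via
    :data:`MISMATCH_MAP`.
    """

    scheme: str = "none"
    count: int = 0
    side: str = "three_prime_flap"
    positions: tuple[int, ...] = ()
    substitution_map: tuple[tuple[str, str], ...] = tuple(
        sorted(MISMATCH_MAP.items())
    )

    def __post_init__(self) -> None:
        if len(self.positions) != self.count:
            raise ValueError("|positions| must equal count")

    def as_atoms(self, ref: str) -> tuple[EditAtom, ...]:
        """Mismatches expressed as 1-nt replacement atoms on the reference."""
        sub = dict(self.substitution_map)
        return tuple(
            EditAtom(p, p + 1, sub[ref[p]]) for p in sorted(self.positions)
        )


@dataclass(frozen=True)
class ExtPegRNA:
    """Assembled ext-pegRNA (DNA alphabet, encoded construct 5'->3')."""

    spacer: str
    scaffold: str
    es: str
    hs: str
    pbs: str
    mismatch_plan: MismatchPlan = field(default_factory=MismatchPlan)
    full: str = ""

    def __post_init__(self) -> None:
        if not self.spacer or not self.scaffold:
            raise ValueError("spacer and scaffold must be non-empty")
        for part, what in [(self.spacer, "spacer"), (self.scaffold, "scaffold"),
                           (self.es, "ES"), (self.hs, "HS"), (self.pbs, "PBS")]:
            _check_dna(part, what)
        expected = (
            self.spacer + self.scaffold + revcomp(self.hs) + revcomp(self.es) + self.pbs
        )
        if self.full and self.full != expected:
            raise ValueError("full sequence inconsistent with components")
        object.__setattr__(self, "full", expected)

    @property
    def extension(self) -> str:
        """3' extension: RTT (revcomp HS+ES) followed by PBS."""
        return revcomp(self.hs) + revcomp(self.es) + self.pbs

    @property
    def rtt(self) -> str:
        return revcomp(self.hs) + revcomp(self.es)

    def as_rna(self) -> str:
        return self.full.replace("T", "U")


def decode_ext_pegrna(
    full: str, scaffold: str, es_len: int, hs_len: int, pbs_len: int
) -> tuple[str, str, str, str]:
    """Recover (spacer, es, hs, pbs) from an encoded construct.

    Inverse of :func:`assemble_ext_pegrna` given the scaffold and the
    component lengths.
    """
    spacer = full[:20]
    rest = full[20:]
    if not rest.startswith(scaffold):
        raise ValueError("scaffold not found after spacer")
    ext = rest[len(scaffold):]
    if len(ext) != hs_len + es_len + pbs_len:
        raise ValueError("extension length does not match component lengths")
    pbs = ext[hs_len + es_len:]
    es = revcomp(ext[hs_len : hs_len + es_len])
    hs = revcomp(ext[:hs_len])
    return spacer, es, hs, pbs


def es_end_for(edit: EditSpec, ext_nick: int) -> int:
    """Reference end of the ES window: max(ext nick, last edited base + 1).

    For an insertion atom at point ``q`` the last edited base is taken
    as ``q`` so the payload falls strictly inside the window.
    """
    last = ext_nick
    for a in edit.atoms:
        last = max(last, a.start + 1 if a.is_insertion else a.end)
    return last


def build_pbs(locus: Locus, ups_nick: int, pbs_len: int = PBS_DEFAULT) -> str:
    """PBS: revcomp of the ``pbs_len`` bases immediately 5' of the ups nick.

    This primes reverse transcription off the genomic 3' end that
    stays attached after excision of the inter-nick fragment.
    """
    if pbs_len <= 0:
        raise ValueError("pbs_len must be positive")
    if ups_nick < pbs_len:
        raise ValueError(
            f"pbs_len {pbs_len} reaches before the locus start (ups nick {ups_nick})"
        )
    if not (PBS_RANGE[0] <= pbs_len <= PBS_RANGE[1]):
        warnings.warn(
            f"PBS length {pbs_len} outside the effective range "
            f"{PBS_RANGE[0]}-{PBS_RANGE[1]} nt (12 nt recommended; "
            "avoid PBS shorter than 9 nt)",
            DesignWarning,
            stacklevel=2,
        )
    return revcomp(locus.sequence[ups_nick - pbs_len : ups_nick])


def build_es(locus: Locus, edit: EditSpec, ups_nick: int, ext_nick: int) -> str:
    """Edit sequence: the exact product the new strand must carry.

    Covers the reference window ``[ups_nick, es_end)`` with all edit
    payloads substituted.  A full inter-nick deletion yields an empty
    ES.
    """
    if edit.start < ups_nick:
        raise EditError(
            f"edit atom at {edit.start} lies upstream of the ups nick {ups_nick}"
        )
    end = es_end_for(edit, ext_nick)
    return apply_edit_window(locus.sequence, edit, ups_nick, end)


def build_hs(locus: Locus, es_end: int, hs_len: int = HS_DEFAULT) -> str:
    """Homologous sequence: genome-identical slice ``[es_end, es_end+hs_len)``."""
    if hs_len <= 0:
        raise ValueError("hs_len must be positive")
    if es_end + hs_len > len(locus):
        raise ValueError(
            f"HS window [{es_end},{es_end + hs_len}) exceeds locus length {len(locus)}"
        )
    if hs_len < HS_DEFAULT:
        warnings.warn(
            f"HS length {hs_len} below recommended 16 nt"
            + ("" if hs_len >= HS_TESTED_MIN else " and below the tested floor of 12 nt"),
            DesignWarning,
            stacklevel=2,
        )
    return locus.sequence[es_end : es_end + hs_len]


def retained_flanks(
    edit: EditSpec, ups_nick: int, ext_nick: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Genome-identical ES flanks adjacent to each nick, as ref intervals.

    Returns ``(five_prime_flank, three_prime_flank)`` where the
    five-prime flank is the maximal retained run starting at the ups
    nick (adjacent to the genomic 5' flap) and the three-prime flank
    the maximal retained run ending at the ext nick (adjacent to the
    genomic 3' flap).  An insertion point breaks a run; an atom
    straddling the ext nick empties the three-prime flank.
    """
    width = ext_nick - ups_nick
    retained = [True] * width
    breaks: set[int] = set()  # insertion point b splits bases b-1 and b
    for a in edit.atoms:
        if a.is_insertion:
            if ups_nick <= a.start <= ext_nick:
                breaks.add(a.start)
        else:
            for p in range(max(a.start, ups_nick), min(a.end, ext_nick)):
                retained[p - ups_nick] = False

    five_end = ups_nick
    if ups_nick not in breaks:
        while five_end < ext_nick and retained[five_end - ups_nick]:
            five_end += 1
            if five_end in breaks:
                break
    three_start = ext_nick
    if ext_nick not in breaks:
        while three_start > ups_nick and retained[three_start - 1 - ups_nick]:
            three_start -= 1
            if three_start in breaks:
                break
    return (ups_nick, five_end), (three_start, ext_nick)


def introduce_mismatches(
    es: str,
    edit: EditSpec,
    ups_nick: int,
    ext_nick: int,
    scheme: str = "consecutive",
    k: int = MISMATCH_K_DEFAULT,
    side: str = "auto",
) -> tuple[str, MismatchPlan]:
    """Substitute ``k`` retained-flank positions of the ES.

    Positions start at the nick-adjacent terminus of the designated
    retained flank (the first nucleotide of the corresponding genomic
    flap) and extend toward the edit region, spaced every 1/3/5 bases
    according to *scheme*.  Substitution uses the fixed transversion
    map A->C, C->A, G->T, T->G; mismatches never fall inside edit
    payloads or the HS.
    """
    if scheme == "none" or k == 0:
        return es, MismatchPlan()
    if scheme not in MISMATCH_SPACING:
        raise ValueError(f"unknown mismatch scheme {scheme!r}")
    spacing = MISMATCH_SPACING[scheme]
    (f5s, f5e), (f3s, f3e) = retained_flanks(edit, ups_nick, ext_nick)
    len5, len3 = f5e - f5s, f3e - f3s
    if side == "auto":
        side = "three_prime_flap" if len3 >= len5 else "five_prime_flap"
    if side == "three_prime_flap":
        flank_len = len3
        ref_positions = [f3e - 1 - spacing * i for i in range(k)]
    elif side == "five_prime_flap":
        flank_len = len5
        ref_positions = [f5s + spacing * i for i in range(k)]
    else:
        raise ValueError(f"unknown mismatch side {side!r}")
    needed = spacing * (k - 1) + 1
    if flank_len < needed:
        max_k = 0 if flank_len <= 0 else (flank_len - 1) // spacing + 1
        raise MismatchInfeasibleError(
            f"retained {side} flank is {flank_len} nt; scheme {scheme!r} with "
            f"k={k} needs {needed} nt (max feasible k={max_k})"
        )

    # Map retained reference positions to ES indices by walking the
    # window product the same way build_es does.
    ref_to_es: dict[int, int] = {}
    cur_ref, cur_es = ups_nick, 0
    for a in edit.atoms:
        for r in range(cur_ref, a.start):
            ref_to_es[r] = cur_es
            cur_es += 1
        cur_es += len(a.payload)
        cur_ref = a.end
    end = es_end_for(edit, ext_nick)
    for r in range(cur_ref, end):
        ref_to_es[r] = cur_es
        cur_es += 1
    assert cur_es == len(es)

    chars = list(es)
    for r in ref_positions:
        i = ref_to_es[r]
        chars[i] = MISMATCH_MAP[chars[i]]
    plan = MismatchPlan(
        scheme=scheme, count=k, side=side, positions=tuple(sorted(ref_positions))
    )
    return "".join(chars), plan


def max_feasible_mismatches(
    edit: EditSpec, ups_nick: int, ext_nick: int, scheme: str, side: str
) -> tuple[str, int]:
    """Resolve side=auto and return (side, largest feasible k) for a scheme."""
    spacing = MISMATCH_SPACING.get(scheme, 1)
    (f5s, f5e), (f3s, f3e) = retained_flanks(edit, ups_nick, ext_nick)
    len5, len3 = f5e - f5s, f3e - f3s
    if side == "auto":
        side = "three_prime_flap" if len3 >= len5 else "five_prime_flap"
    flank = len3 if side == "three_prime_flap" else len5
    return side, 0 if flank <= 0 else (flank - 1) // spacing + 1


def edit_with_mismatches(edit: EditSpec, plan: MismatchPlan, ref: str) -> EditSpec:
    """Combined edit: original atoms plus 1-nt mismatch replacements."""
    if plan.count == 0:
        return edit
    atoms = sorted(
        edit.atoms + plan.as_atoms(ref), key=lambda a: (a.start, a.end)
    )
    return EditSpec(atoms=tuple(atoms), label=edit.label + f" +{plan.count}mm")


def assemble_ext_pegrna(
    spacer: str,
    scaffold: str,
    es: str,
    hs: str,
    pbs: str,
    mismatch_plan: MismatchPlan | None = None,
) -> ExtPegRNA:
    """Assemble the encoded construct spacer+scaffold+rc(HS)+rc(ES)+PBS."""
    return ExtPegRNA(
        spacer=spacer,
        scaffold=scaffold,
        es=es,
        hs=hs,
        pbs=pbs,
        mismatch_plan=mismatch_plan or MismatchPlan(),
    )


def build_sgrna(spacer: str, scaffold: str, u6_g: bool = False) -> str:
    """Plain sgRNA: spacer + scaffold, with optional U6 leading G."""
    _check_dna(spacer, "spacer")
    if u6_g and not spacer.startswith("G"):
        spacer = "G" + spacer
    return spacer + scaffold
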