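"""Seeded synthetic loci and read sets with known ground truth.

Everything downstream of guide search needs loci whose guide geometry
is known exactly, and the quantifier needs read sets whose outcome
composition is planted.  Both generators are fully seeded and byte-
reproducible.

Loci are built on a background free of GG/CC dinucleotides so the
only NGG guide sites are the planted ones; each planting writes a
20-nt protospacer followed by an AGG PAM (forward) or its mirror
(reverse).  Read sets allocate class counts either exactly (largest-
remainder rounding, making golden tests exact) or by multinomial
draw, with optional uniform per-base substitution errors; indel reads
receive a 1-10 nt deletion or insertion at one of the nick positions,
where real prime-editing byproducts arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_core import EditAtom, EditSpec, Locus, revcomp

_BASES = np.array(list("ACGT"))


class PlantingError(ValueError):
    """Requested plantings cannot be realized on the locus."""


@dataclass(frozen=True)
class LocusRecipe:
    """Recipe for a locus with planted guide sites.

    ``planted`` holds ``(strand, block_start)`` pairs where the 23-nt
    site block occupies ``[block_start, block_start+23)`` on the
    working strand: forward blocks are protospacer+PAM (nick at
    ``block_start+17``), reverse blocks are PAM+protospacer in mirror
    orientation (nick at ``block_start+6``).
    """

    seed: int
    length: int
    planted: tuple[tuple[str, int], ...] = ()
    name: str = "synthetic_locus"

    def nicks(self) -> tuple[int, ...]:
        return tuple(
            s + (17 if strand == "+" else 6) for strand, s in self.planted
        )


def recipe_for_nicks(
    seed: int, length: int, nicks: tuple[int, ...], strand: str = "+",
    name: str = "synthetic_locus",
) -> LocusRecipe:
    """Convenience recipe placing same-strand sites by desired nick index."""
    off = 17 if strand == "+" else 6
    planted = tuple((strand, n - off) for n in nicks)
    return LocusRecipe(seed=seed, length=length, planted=planted, name=name)


def _background(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence containing no GG or CC dinucleotide."""
    seq: list[str] = []
    prev = ""
    for _ in range(length):
        choices = [b for b in "ACGT" if not (prev == b and b in "GC")]
        seq.append(choices[rng.integers(len(choices))])
        prev = seq[-1]
    return seq


def _clean_protospacer(rng: np.random.Generator) -> str:
    """20-mer with no GG/CC and non-G/C terminal bases (junction-safe)."""
    while True:
        chars = _background(rng, 20)
        if chars[0] not in "GC" and chars[-1] not in "GC":
            return "".join(chars)


def make_locus(recipe: LocusRecipe) -> Locus:
    """Build the locus; same seed gives a byte-identical sequence."""
    rng = np.random.default_rng(recipe.seed)
    blocks = sorted(recipe.planted, key=lambda p: p[1])
    for (_, a), (_, b) in zip(blocks, blocks[1:]):
        if b < a + 23:
            raise PlantingError("planted site blocks overlap")
    if blocks and (blocks[0][1] < 0 or blocks[-1][1] + 23 > recipe.length):
        raise PlantingError("planted site outside the locus")

    seq = _background(rng, recipe.length)
    for strand, start in blocks:
        proto = _clean_protospacer(rng)
        if strand == "+":
            block = proto + "AGG"
        elif strand == "-":
            block = revcomp(proto + "AGG")  # CCT + rc(protospacer)
        else:
            raise PlantingError(f"bad strand {strand!r}")
        seq[start : start + 23] = list(block)
        # Guard the junctions so no unintended GG/CC forms.
        if start > 0 and seq[start - 1] in "GC":
            seq[start - 1] = "A"
        if start + 23 < recipe.length and seq[start + 23] in "GC":
            seq[start + 23] = "A"
    locus = Locus(name=recipe.name, sequence="".join(seq))
    _assert_clean(locus, blocks)
    return locus


def _assert_clean(locus: Locus, blocks: list[tuple[str, int]]) -> None:
    from .guide_search import find_guide_sites

    got = {(g.strand, g.protospacer_start) for g in find_guide_sites(locus, "both")}
    want = {
        (strand, start if strand == "+" else start + 3)
        for strand, start in blocks
    }
    if got != want:
        raise PlantingError(
            f"locus has unintended or missing guide sites: got {sorted(got)}, "
            f"wanted {sorted(want)}"
        )


@dataclass(frozen=True)
class ReadRecipe:
    """Composition of a synthetic amplicon read set.

    Fractions are of intended / indel-containing / unedited reads; the
    remainder (if any) becomes substitution-only reads.  ``mode`` is
    ``deterministic_allocation`` (largest-remainder rounding; exact) or
    ``multinomial``.
    """

    seed: int
    n_reads: int
    f_intended: float
    f_indel: float
    f_unedited: float
    error_rate: float = 0.0
    indel_size_range: tuple[int, int] = (1, 10)
    nick_positions: tuple[int, ...] = ()
    sub_position: int | None = None  # ref/edited-allele index for substituted reads
    sub_on_edited: bool = False
    mode: str = "deterministic_allocation"

    def fractions(self) -> tuple[float, float, float, float]:
        rest = 1.0 - (self.f_intended + self.f_indel + self.f_unedited)
        if rest < -1e-9:
            raise ValueError("class fractions sum to more than 1")
        return (self.f_intended, self.f_indel, self.f_unedited, max(rest, 0.0))


def largest_remainder(n: int, fractions: tuple[float, ...]) -> tuple[int, ...]:
    """Integer allocation of ``n`` by largest remainder (ties by index)."""
    exact = [n * f for f in fractions]
    base = [int(x) for x in exact]
    short = n - sum(base)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i)
    )
    for i in order[:short]:
        base[i] += 1
    return tuple(base)


def _mutate(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[rng.integers(3)]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = _mutate(rng, chars[i])
    return "".join(chars)


def simulate_reads(
    ref_allele: str, edited_allele: str, recipe: ReadRecipe
) -> list[tuple[str, str]]:
    """Generate (name, sequence) reads with the planted composition."""
    rng = np.random.default_rng(recipe.seed)
    fracs = recipe.fractions()
    if recipe.mode == "deterministic_allocation":
        counts = largest_remainder(recipe.n_reads, fracs)
    elif recipe.mode == "multinomial":
        counts = tuple(rng.multinomial(recipe.n_reads, fracs))
    else:
        raise ValueError(f"unknown mode {recipe.mode!r}")
    n_int, n_ind, n_un, n_sub = counts
    if n_sub and recipe.sub_position is None:
        raise ValueError("substituted reads requested but sub_position unset")

    reads: list[tuple[str, str]] = []
    idx = 0

    def emit(label: str, seq: str) -> None:
        nonlocal idx
        reads.append((f"read_{idx:05d}_{label}", _apply_errors(rng, seq, recipe.error_rate)))
        idx += 1

    for _ in range(n_int):
        emit("intended", edited_allele)
    lo, hi = recipe.indel_size_range
    for _ in range(n_ind):
        if not recipe.nick_positions:
            raise ValueError("indel reads requested but nick_positions unset")
        nick = recipe.nick_positions[rng.integers(len(recipe.nick_positions))]
        size = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.5 and nick + size <= len(ref_allele):
            seq = ref_allele[:nick] + ref_allele[nick + size :]
        else:
            ins = "".join(_BASES[rng.integers(4, size=size)])
            seq = ref_allele[:nick] + ins + ref_allele[nick:]
        emit("indel", seq)
    for _ in range(n_un):
        emit("unedited", ref_allele)
    for _ in range(n_sub):
        template = edited_allele if recipe.sub_on_edited else ref_allele
        p = recipe.sub_position
        seq = template[:p] + _mutate(rng, template[p]) + template[p + 1 :]
        emit("substituted", seq)
    return reads


def read_recipe_for_design(design, locus, seed: int, n_reads: int,
                           f_intended: float, f_indel: float, f_unedited: float,
                           **kwargs) -> ReadRecipe:
    """Recipe wired to a design: indels at the design's nicks, the
    substituted-class change inside the edit region."""
    from .amplicon_quant import quant_spec_from_design

    spec = quant_spec_from_design(locus, design)
    nicks = [design.pair.ups.nick, design.pair.ext.nick]
    if design.helper is not None:
        nicks.append(design.helper.nick)
    if spec.ed_check_positions:
        sub_pos, sub_on_edited = min(spec.ed_check_positions), True
    elif spec.ref_check_positions:
        sub_pos, sub_on_edited = min(spec.ref_check_positions), False
    else:
        sub_pos, sub_on_edited = None, False
    return ReadRecipe(
        seed=seed, n_reads=n_reads, f_intended=f_intended, f_indel=f_indel,
        f_unedited=f_unedited, nick_positions=tuple(nicks),
        sub_position=sub_pos, sub_on_edited=sub_on_edited, **kwargs,
    )


def write_reads_fastq(reads: list[tuple[str, str]], path: str) -> None:
    """Write reads as FASTQ with constant Q30 qualities."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'?' * len(seq)}\n")


def write_reads_fasta(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f">{name}\n{seq}\n")


def write_locus_fasta(locus: Locus, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{locus.name}\n")
        for i in range(0, len(locus.sequence), 70):
            fh.write(locus.sequence[i : i + 70] + "\n")


def random_edit(
    rng: np.random.Generator,
    ups_nick: int,
    ext_nick: int,
    locus_len: int,
    kind: str | None = None,
    hs_len: int = 16,
) -> EditSpec:
    """Random edit compatible with a planted nick pair.

    Kinds: deletion (1-88 bp), replacement (payload up to 88 bp),
    insertion (up to 100 bp), both_sides (inter-nick replacement plus a
    1-nt replacement downstream of the ext nick).  Geometry respects
    the ups nick and leaves room for the HS.
    """
    kind = kind or ("deletion", "replacement", "insertion", "both_sides")[
        rng.integers(4)
    ]
    dcn = ext_nick - ups_nick
    max_end = locus_len - hs_len

    def span(max_len: int) -> tuple[int, int]:
        width = int(rng.integers(1, min(max_len, dcn) + 1))
        start = ups_nick + int(rng.integers(0, dcn - width + 1))
        return start, start + width

    if kind == "deletion":
        s, e = span(88)
        atoms = [EditAtom(s, e, "")]
    elif kind == "replacement":
        s, e = span(dcn)
        payload = "".join(_BASES[rng.integers(4, size=rng.integers(1, 89))])
        atoms = [EditAtom(s, e, payload)]
    elif kind == "insertion":
        pos = ups_nick + int(rng.integers(0, dcn))
        payload = "".join(_BASES[rng.integers(4, size=rng.integers(1, 101))])
        atoms = [EditAtom(pos, pos, payload)]
    elif kind == "both_sides":
        s, e = span(dcn)
        payload = "".join(_BASES[rng.integers(4, size=rng.integers(1, 45))])
        down = ext_nick + int(rng.integers(0, max(1, min(8, max_end - ext_nick - 1))))
        down_base = _BASES[rng.integers(4)]
        atoms = [EditAtom(s, e, payload), EditAtom(down, down + 1, str(down_base))]
    else:
        raise ValueError(f"unknown edit kind {kind!r}")
    return EditSpec(atoms=tuple(atoms), label=f"random {kind}")
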