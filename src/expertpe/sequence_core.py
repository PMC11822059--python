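"""Sequence and coordinate primitives.

A :class:`Locus` is a short (kilobase-scale) reference region whose
"working strand" is the strand carrying both protospacers of a dual
cis-nick prime-editing design.  Edits are expressed as ordered atomic
substitutions of half-open intervals by replacement payloads
(:class:`EditSpec`), in 0-based working-strand coordinates.

The field convention of naming edits relative to a nick ("-37to-1",
"+1") has no position 0: -1 is the base immediately 5' of the nick and
+1 the base immediately 3' of it.  :func:`nick_relative_interval`
translates that notation into absolute coordinates.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = re.compile(r"^[ACGT]*$")


class AlphabetError(ValueError):
    """Sequence contains characters outside A/C/G/T."""


class EditError(ValueError):
    """Edit specification is malformed or inconsistent with the locus."""


def _check_dna(seq: str, what: str = "sequence") -> str:
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise AlphabetError(f"{what} contains non-ACGT characters: {bad}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Locus:
    """A named reference DNA sequence with a local coordinate frame.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"VEGFA_1"``.
    sequence : str
        5'->3' working-strand sequence; lowercase is accepted and
        uppercased, ambiguity codes are rejected.
    origin_offset : int
        Added to coordinates when reporting (default 0).
    """

    name: str
    sequence: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("locus sequence must be non-empty")
        _check_dna(seq, f"locus {self.name!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EditAtom:
    """One atomic edit: replace working-strand interval [start, end) by payload.

    Deletion: non-empty interval, empty payload.  Insertion: zero-length
    interval, non-empty payload (inserted before base ``start``).
    Replacement: both non-empty.
    """

    start: int
    end: int
    payload: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise EditError(f"bad interval [{self.start},{self.end})")
        payload = self.payload.upper()
        _check_dna(payload, "payload")
        if self.end == self.start and not payload:
            raise EditError("degenerate atom: empty interval and empty payload")
        object.__setattr__(self, "payload", payload)

    @property
    def kind(self) -> str:
        if self.end == self.start:
            return "insertion"
        return "deletion" if not self.payload else "replacement"

    @property
    def is_insertion(self) -> bool:
        return self.end == self.start


@dataclass(frozen=True)
class EditSpec:
    """Ordered, non-overlapping atomic edits defining one intended product."""

    atoms: tuple[EditAtom, ...]
    label: str = ""

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        if not atoms:
            raise EditError("EditSpec needs at least one atom")
        object.__setattr__(self, "atoms", atoms)
        prev_end = None
        prev_start = None
        for a in atoms:
            if prev_end is not None:
                if a.start < prev_end or (a.start == prev_start):
                    raise EditError("atoms must be sorted and non-overlapping")
            prev_end, prev_start = a.end, a.start

    @property
    def start(self) -> int:
        return self.atoms[0].start

    @property
    def end(self) -> int:
        return max(a.end for a in self.atoms)

    def net_insertion(self) -> int:
        """Net length change of the product (payload minus interval lengths)."""
        return sum(len(a.payload) - (a.end - a.start) for a in self.atoms)

    def check_bounds(self, locus: Locus) -> None:
        if self.end > len(locus):
            raise EditError(
                f"edit extends to {self.end} beyond locus length {len(locus)}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "atoms": [
                    {"start": a.start, "end": a.end, "payload": a.payload}
                    for a in self.atoms
                ],
                "label": self.label,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EditSpec":
        doc = json.loads(text)
        atoms = tuple(
            EditAtom(a["start"], a["end"], a.get("payload", ""))
            for a in doc["atoms"]
        )
        return cls(atoms=atoms, label=doc.get("label", ""))


def apply_edit(locus: Locus | str, edit: EditSpec) -> str:
    """Apply all atoms of *edit* to the locus sequence, left to right.

    Returns the product sequence.  Length bookkeeping:
    ``len(product) = len(ref) - sum(interval widths) + sum(payload lengths)``.
    """
    ref = locus.sequence if isinstance(locus, Locus) else locus
    for a in edit.atoms:
        if a.end > len(ref):
            raise EditError(f"atom [{a.start},{a.end}) out of bounds (len {len(ref)})")
    out: list[str] = []
    cur = 0
    for a in edit.atoms:
        out.append(ref[cur : a.start])
        out.append(a.payload)
        cur = a.end
    out.append(ref[cur:])
    return "".join(out)


def apply_edit_window(ref: str, edit: EditSpec, start: int, end: int) -> str:
    """Product sequence restricted to the reference window [start, end).

    All atoms must lie within the window; an insertion at position
    ``end`` is outside it (half-open convention).
    """
    out: list[str] = []
    cur = start
    for a in edit.atoms:
        if a.start < start or a.end > end or (a.is_insertion and a.start >= end):
            raise EditError(
                f"atom [{a.start},{a.end}) outside window [{start},{end})"
            )
        out.append(ref[cur : a.start])
        out.append(a.payload)
        cur = a.end
    out.append(ref[cur:end])
    return "".join(out)


def nick_relative_interval(label_start: int, label_end: int, nick: int) -> tuple[int, int]:
    """Map nick-relative labels to an absolute half-open interval.

    Position ``-k`` is the base at absolute index ``nick - k``; position
    ``+k`` the base at index ``nick + k - 1`` (there is no position 0,
    so -1|+1 straddle the nick).  ``(-37, -1)`` with nick 100 gives
    ``[63, 100)``.
    """
    if label_start == 0 or label_end == 0:
        raise EditError("nick-relative labels have no position 0")
    if label_start > label_end:
        raise EditError("label start must not exceed label end")

    def _abs(k: int) -> int:
        return nick - (-k) if k < 0 else nick + k - 1

    start = _abs(label_start)
    end = _abs(label_end) + 1
    if start < 0:
        raise EditError(f"interval [{start},{end}) extends before the locus")
    return start, end


def interval_to_nick_labels(start: int, end: int, nick: int) -> tuple[int, int]:
    """Inverse of :func:`nick_relative_interval` for a non-empty interval."""
    if end <= start:
        raise EditError("labeling requires a non-empty interval")

    def _lab(i: int) -> int:
        return i - nick + 1 if i >= nick else i - nick

    return _lab(start), _lab(end - 1)


def read_locus(path: str, name: str | None = None) -> Locus:
    """Read the first record of a FASTA file as a :class:`Locus`.

    Extra records are ignored with a warning.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning(
            "FASTA %s has %d records; using only the first (%s)",
            path, len(records), records[0].id,
        )
    rec = records[0]
    return Locus(name=name or rec.id, sequence=str(rec.seq))


_EDIT_ATOM_RE = re.compile(
    r"^(?:(?P<start>\d+)-(?P<end>\d+):(?P<op2>replace|delete)(?::(?P<seq2>[ACGTacgt]+))?"
    r"|(?P<pos>\d+):(?P<op1>insert):(?P<seq1>[ACGTacgt]+))$"
)


def parse_edit_string(text: str, label: str = "") -> EditSpec:
    """Parse the compact CLI edit dialect.

    Grammar (comma-separated atoms, absolute 0-based half-open coords)::

        START-END:replace:SEQ | START-END:delete | POS:insert:SEQ

    Example: ``"63-100:replace:ACG...,120:insert:GATTACA"``.
    """
    atoms = []
    for part in text.split(","):
        part = part.strip()
        m = _EDIT_ATOM_RE.match(part)
        if not m:
            raise EditError(f"cannot parse edit atom {part!r}")
        if m.group("pos") is not None:
            pos = int(m.group("pos"))
            atoms.append(EditAtom(pos, pos, m.group("seq1")))
        else:
            start, end = int(m.group("start")), int(m.group("end"))
            op = m.group("op2")
            seq = m.group("seq2") or ""
            if op == "replace" and not seq:
                raise EditError(f"replace atom {part!r} needs a payload")
            if op == "delete" and seq:
                raise EditError(f"delete atom {part!r} must not carry a payload")
            atoms.append(EditAtom(start, end, seq))
    atoms.sort(key=lambda a: (a.start, a.end))
    return EditSpec(atoms=tuple(atoms), label=label or text)


def rc_edit(edit: EditSpec, locus_len: int) -> EditSpec:
    """Map an edit into the reverse-complement coordinate frame."""
    atoms = tuple(
        EditAtom(locus_len - a.end, locus_len - a.start,
                 revcomp(a.payload) if a.payload else "")
        for a in reversed(edit.atoms)
    )
    return EditSpec(atoms=atoms, label=edit.label + " (rc frame)")
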