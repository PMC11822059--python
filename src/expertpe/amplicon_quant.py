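"""Amplicon-read outcome classification and editing statistics.

Reads are globally aligned (Needleman-Wunsch, match +1 / mismatch -1 /
linear gap -2) against both the reference allele and the predicted
edited allele; the higher-scoring allele wins (ties go to the edited
allele).  Within a quantification window spanning the nick-to-edit
region plus a margin, a read is

* ``intended``   — best on the edited allele, gap-free in the window,
  and matching the edited allele at every edited position (payloads
  and deliberate mismatch positions);
* ``indel``      — best alignment has >= 1 gap inside the window;
* ``unedited``   — best on the reference, gap-free, untouched at the
  edit intervals;
* ``substituted``— gap-free but carrying window changes inconsistent
  with both alleles;
* ``unassigned`` — does not span the window.

Efficiency is the fraction of intended reads among all reads, the
indel rate the fraction of indel-containing reads, and product purity
the ratio intended:indel, following the standard deep-sequencing
readout for prime editing.  Substitution-only reads count toward
neither intended nor indels, which partitions totals the same way the
two read-count formulas do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from numba import njit

from .design_scoring import ExpertDesign
from .sequence_core import Locus

MATCH, MISMATCH, GAP = 1, -1, -2

_ENC = np.zeros(128, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: int


@njit(cache=True)
def _nw_fill(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    m, n = a.shape[0], b.shape[0]
    H = np.empty((m + 1, n + 1), np.int32)
    P = np.empty((m + 1, n + 1), np.uint8)  # 0 diag, 1 up (base in a), 2 left (base in b)
    H[0, 0] = 0
    P[0, 0] = 0
    for j in range(1, n + 1):
        H[0, j] = j * gap
        P[0, j] = 2
    for i in range(1, m + 1):
        H[i, 0] = i * gap
        P[i, 0] = 1
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if ai == b[j - 1] else mismatch
            best = H[i - 1, j - 1] + s
            p = 0
            left = H[i, j - 1] + gap  # gap in a, consumes b[j-1]
            if left > best:
                best = left
                p = 2
            up = H[i - 1, j] + gap  # gap in b, consumes a[i-1]
            if up > best:
                best = up
                p = 1
            H[i, j] = best
            P[i, j] = p
    return H[m, n], P


def align_global(
    a: str, b: str, match: int = MATCH, mismatch: int = MISMATCH, gap: int = GAP
) -> Alignment:
    """Optimal global alignment with deterministic traceback.

    Tie-breaking prefers a match/mismatch column over a gap in *a*
    over a gap in *b*.
    """
    if not a or not b:
        raise ValueError("align_global requires non-empty sequences")
    score, P = _nw_fill(
        _ENC[np.frombuffer(a.encode(), dtype=np.uint8)],
        _ENC[np.frombuffer(b.encode(), dtype=np.uint8)],
        match, mismatch, gap,
    )
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
    return Alignment("".join(reversed(ra)), "".join(reversed(rb)), int(score))


@dataclass(frozen=True)
class QuantSpec:
    """Everything the classifier needs, per allele.

    Windows are half-open intervals on the respective allele;
    ``*_check_positions`` are the allele positions that define the edit
    (payload bases and deliberate mismatch positions on the edited
    allele; the replaced/deleted reference bases on the reference
    allele).
    """

    ref_allele: str
    edited_allele: str
    ref_window: tuple[int, int]
    ed_window: tuple[int, int]
    ref_check_positions: frozenset[int]
    ed_check_positions: frozenset[int]


def quant_spec_from_design(locus: Locus, d: ExpertDesign, w: int = 10) -> QuantSpec:
    """Build the classification spec for one validated design."""
    from .construct_builder import edit_with_mismatches

    ref = locus.sequence
    u = d.pair.ups.nick
    combined = edit_with_mismatches(d.edit, d.ext_pegrna.mismatch_plan, ref)
    ed = d.predicted_allele
    ref_positions: set[int] = set()
    ed_positions: set[int] = set()
    shift = 0  # edited-allele index minus reference index, so far
    for a in combined.atoms:
        ref_positions.update(range(a.start, a.end))
        ed_positions.update(range(a.start + shift, a.start + shift + len(a.payload)))
        shift += len(a.payload) - (a.end - a.start)
    quant_end_ref = d.es_end
    quant_end_ed = u + len(d.ext_pegrna.es)
    ref_win = (max(0, u - w), min(len(ref), quant_end_ref + w))
    ed_win = (max(0, u - w), min(len(ed), quant_end_ed + w))
    return QuantSpec(
        ref_allele=ref,
        edited_allele=ed,
        ref_window=ref_win,
        ed_window=ed_win,
        ref_check_positions=frozenset(ref_positions),
        ed_check_positions=frozenset(ed_positions),
    )


def _inspect(read: str, allele: str, window: tuple[int, int],
             checks: frozenset[int]) -> tuple[bool, bool, int]:
    """Align read to allele; report (gap_in_window, checks_ok, score)."""
    aln = align_global(read, allele)
    ws, we = window
    apos = 0  # allele bases consumed
    gap_in_window = False
    checks_ok = True
    for rc, ac in zip(aln.aligned_a, aln.aligned_b):
        if ac != "-" and rc != "-":
            if apos in checks and rc != ac:
                checks_ok = False
            apos += 1
        elif ac != "-":  # deletion in read at allele position apos
            if ws <= apos < we:
                gap_in_window = True
            if apos in checks:
                checks_ok = False
            apos += 1
        else:  # insertion in read at allele boundary apos
            if ws < apos < we:
                gap_in_window = True
    return gap_in_window, checks_ok, aln.score


def classify_read(read: str, spec: QuantSpec) -> str:
    """Assign one read to {intended, indel, unedited, substituted, unassigned}."""
    # A read shorter than the quantification window cannot span it.
    min_span = min(
        spec.ref_window[1] - spec.ref_window[0],
        spec.ed_window[1] - spec.ed_window[0],
    )
    if len(read) < min_span:
        return "unassigned"
    # Exact matches need no alignment (common case for clean amplicons).
    if read == spec.edited_allele:
        return "intended"
    if read == spec.ref_allele:
        return "unedited"
    ref_gap, ref_ok, ref_score = _inspect(
        read, spec.ref_allele, spec.ref_window, spec.ref_check_positions
    )
    ed_gap, ed_ok, ed_score = _inspect(
        read, spec.edited_allele, spec.ed_window, spec.ed_check_positions
    )
    if ed_score >= ref_score:  # ties go to the edited allele
        gap, ok = ed_gap, ed_ok
        best_edited = True
    else:
        gap, ok = ref_gap, ref_ok
        best_edited = False
    if gap:
        return "indel"
    if best_edited:
        return "intended" if ok else "substituted"
    return "unedited" if ok else "substituted"


_INF = float("inf")


@dataclass(frozen=True)
class QuantResult:
    n_total: int
    n_intended: int
    n_indel: int
    n_unedited: int
    n_substituted: int
    n_unassigned: int

    def __post_init__(self) -> None:
        parts = (self.n_intended + self.n_indel + self.n_unedited
                 + self.n_substituted + self.n_unassigned)
        if parts != self.n_total:
            raise ValueError("class counts do not sum to n_total")

    @property
    def efficiency(self) -> float:
        """Intended-edit reads as a percentage of all reads."""
        return 100.0 * self.n_intended / self.n_total

    @property
    def indel_rate(self) -> float:
        """Indel-containing reads as a percentage of all reads."""
        return 100.0 * self.n_indel / self.n_total

    @property
    def purity(self) -> float:
        """Product purity: intended:indel ratio (inf when no indels)."""
        if self.n_indel == 0:
            return _INF
        return self.n_intended / self.n_indel

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_intended": self.n_intended,
            "n_indel": self.n_indel,
            "n_unedited": self.n_unedited,
            "n_substituted": self.n_substituted,
            "n_unassigned": self.n_unassigned,
            "efficiency_pct": self.efficiency,
            "indel_rate_pct": self.indel_rate,
            "purity": "inf" if math.isinf(self.purity) else self.purity,
        }


def quantify(reads: list[str], spec: QuantSpec) -> QuantResult:
    """Classify every read and derive the summary statistics."""
    if not reads:
        raise ValueError("quantify requires at least one read")
    counts = {"intended": 0, "indel": 0, "unedited": 0,
              "substituted": 0, "unassigned": 0}
    for r in reads:
        counts[classify_read(r, spec)] += 1
    return QuantResult(
        n_total=len(reads),
        n_intended=counts["intended"],
        n_indel=counts["indel"],
        n_unedited=counts["unedited"],
        n_substituted=counts["substituted"],
        n_unassigned=counts["unassigned"],
    )


def fold_change(treatment_pct: float, control_pct: float, digits: int = 1) -> float:
    """Treatment/control ratio, rounded half-up to ``digits``.

    E.g. efficiencies 9.13% vs 0.23% give a 39.7-fold change.
    Returns ``inf`` for a zero control (undefined marker).
    """
    if control_pct == 0:
        return _INF
    q = Decimal(str(treatment_pct)) / Decimal(str(control_pct))
    return float(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


def read_sequences(path: str) -> list[str]:
    """Load read sequences from FASTA or FASTQ (qualities ignored)."""
    from Bio import SeqIO

    fmt = "fastq" if str(path).lower().endswith(("fastq", "fq")) else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(path, fmt)]
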