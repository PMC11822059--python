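"""Heuristic ranking of candidate dual cis-nick designs.

The score aggregates three graded geometric components — DCN, PBS
length and HS length — each normalized to [0,1] and weighted equally
by default (the underlying evidence is ordinal, so the weights are
config, not ground truth).  Hard violations (DCN below 25 nt) zero
the score.  Everything else the empirical rules say is attached as a
non-numeric flag: a mismatch recommendation when a long retained
flank would let the genomic flap re-hybridize, a Helper-gRNA
recommendation for large edits, cautions for very large insertions,
TTTT pol III terminator runs in encoded guides, and re-cut potential
when the edited product still carries an intact protospacer+PAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .construct_builder import ExtPegRNA
from .guide_search import GuidePair, GuideSite
from .sequence_core import EditSpec

#: Flag codes (non-numeric; never move the score by themselves).
HARD_DCN = "HARD_DCN"
SHORT_PBS = "SHORT_PBS"
LONG_PBS = "LONG_PBS"
SHORT_HS = "SHORT_HS"
MISMATCH_RECOMMENDED = "MISMATCH_RECOMMENDED"
MISMATCH_K_REDUCED = "MISMATCH_K_REDUCED"
HELPER_RECOMMENDED = "HELPER_RECOMMENDED"
LARGE_INSERTION = "LARGE_INSERTION"
TTTT_RUN = "TTTT_RUN"
RECUT = "RECUT"

DEFAULT_WEIGHTS = {"dcn": 1 / 3, "pbs": 1 / 3, "hs": 1 / 3}

#: Retained-flank length at which flap re-hybridization visibly
#: suppresses editing, so mismatches should be introduced.
FLAP_MISMATCH_THRESHOLD = 14
#: ES length above which a Helper gRNA measurably improves efficiency.
HELPER_ES_THRESHOLD = 70
#: Net insertion size beyond which efficiency drops sharply.
LARGE_INSERTION_THRESHOLD = 50


@dataclass
class ExpertDesign:
    """One candidate solution: ups-sgRNA + ext-pegRNA (+ Helper gRNA)."""

    pair: GuidePair
    ext_pegrna: ExtPegRNA
    ups_sgrna: str
    edit: EditSpec
    es_end: int
    strand: str = "+"
    helper: GuideSite | None = None
    helper_sgrna: str | None = None
    edit_nick_distance_3p: int = 0  # retained flank between edit and ext nick ("m")
    edit_nick_distance_5p: int = 0
    score: float = 0.0
    flags: tuple[str, ...] = ()
    predicted_allele: str = ""
    editor_label: str = "EXPERT"

    @property
    def dcn(self) -> int:
        return self.pair.dcn

    @property
    def pbs_len(self) -> int:
        return len(self.ext_pegrna.pbs)

    @property
    def hs_len(self) -> int:
        return len(self.ext_pegrna.hs)


def _dcn_credit(dcn: int) -> float:
    if dcn < 25:
        return 0.0
    if 32 <= dcn <= 40:
        return 1.0
    if dcn < 32:  # 25..31: approaching the optimum from the steric floor
        return 0.5 + 0.5 * (dcn - 25) / 7
    if dcn <= 71:  # 41..71: robust but declining reporter signal
        return 1.0 - 0.75 * (dcn - 40) / 31
    return 0.1  # beyond 71: barely detectable regime


def _pbs_credit(pbs_len: int) -> float:
    if pbs_len == 12:
        return 1.0
    if 9 <= pbs_len <= 16:
        return 1.0 - 0.05 * abs(pbs_len - 12)
    return 0.2


def _hs_credit(hs_len: int) -> float:
    if hs_len >= 16:
        return 1.0
    if 12 <= hs_len <= 15:
        return 0.5 + 0.5 * (hs_len - 12) / 4
    return 0.2


def score_design(
    d: ExpertDesign, weights: dict[str, float] | None = None
) -> tuple[float, tuple[str, ...]]:
    """Deterministic additive score plus coded warning flags.

    Pure function of the design; never raises on a structurally valid
    design.  A DCN below the 25-nt hard floor zeroes the score.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    total_w = sum(w[k] for k in ("dcn", "pbs", "hs"))
    flags: list[str] = []

    dcn_c = _dcn_credit(d.dcn)
    if d.dcn < 25:
        flags.append(HARD_DCN)
    pbs_c = _pbs_credit(d.pbs_len)
    if d.pbs_len < 9:
        flags.append(SHORT_PBS)
    elif d.pbs_len > 16:
        flags.append(LONG_PBS)
    hs_c = _hs_credit(d.hs_len)
    if d.hs_len < 12:
        flags.append(SHORT_HS)

    plan = d.ext_pegrna.mismatch_plan
    max_flank = max(d.edit_nick_distance_3p, d.edit_nick_distance_5p)
    if max_flank >= FLAP_MISMATCH_THRESHOLD and plan.count == 0:
        flags.append(MISMATCH_RECOMMENDED)
    if len(d.ext_pegrna.es) >= HELPER_ES_THRESHOLD and d.helper is None:
        flags.append(HELPER_RECOMMENDED)
    if d.edit.net_insertion() > LARGE_INSERTION_THRESHOLD:
        flags.append(LARGE_INSERTION)

    # Pol III terminator runs in encoded guides; the standard scaffold
    # itself carries a TTTT and is excluded from the scan.
    non_scaffold = d.ext_pegrna.spacer + d.ext_pegrna.extension
    ups_spacer = d.pair.ups.spacer
    helper_spacer = d.helper.spacer if d.helper else ""
    if "TTTT" in non_scaffold or "TTTT" in ups_spacer or "TTTT" in helper_spacer:
        flags.append(TTTT_RUN)

    if d.predicted_allele:
        for site in (d.pair.ups, d.pair.ext):
            if site.site_23mer() in d.predicted_allele:
                flags.append(RECUT)
                break

    if d.dcn < 25:
        score = 0.0
    else:
        score = (w["dcn"] * dcn_c + w["pbs"] * pbs_c + w["hs"] * hs_c) / total_w
    return round(score, 6), tuple(flags)


def attach_score(d: ExpertDesign, weights: dict[str, float] | None = None) -> ExpertDesign:
    score, flags = score_design(d, weights)
    extra = tuple(f for f in d.flags if f == MISMATCH_K_REDUCED)
    return replace(d, score=score, flags=flags + extra)


def rank_designs(designs: list[ExpertDesign]) -> list[ExpertDesign]:
    """Stable sort: score desc, |DCN - 36| asc, ext nick asc.

    36 nt is the midpoint of the optimal DCN window and breaks ties
    deterministically.
    """
    return sorted(
        designs,
        key=lambda d: (-d.score, abs(d.dcn - 36), d.pair.ext.nick),
    )
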