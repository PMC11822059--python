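"""SpCas9 NGG guide-site enumeration and cis-nick pair assembly.

The dual cis-nick strategy needs two nicks on the *same* strand: an
upstream sgRNA (ups-sgRNA) nick and the extended-pegRNA (ext-pegRNA)
nick downstream of it.  The distance between the two cis nicks (DCN)
is the central geometric parameter: editing peaks for DCN in 32-40 nt
and collapses at 24 nt or below (steric clash of adjacent nickases),
so 25 nt is the hard floor.  Reporter data supports a permissive range
up to 96 nt.

SpCas9 H840A nicks the protospacer-carrying (PAM) strand 3 nt 5' of
the PAM, i.e. between protospacer positions 17 and 18.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .sequence_core import EditSpec, Locus, revcomp

logger = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_OFFSET = 17  # nick index = protospacer start + 17 (3 nt 5' of PAM)

DCN_WINDOW_DEFAULT = (32, 40)   # endogenous-locus optimum
DCN_WINDOW_RELAXED = (25, 71)   # robust reporter signal
DCN_WINDOW_PERMISSIVE = (25, 96)  # detectable reporter signal
DCN_HARD_MIN = 25               # DCN <= 24 nt is rejected outright


class GeometryError(ValueError):
    """Requested edit cannot be reached by any cis-nick pair."""


@dataclass(frozen=True)
class GuideSite:
    """A 20-nt SpCas9 protospacer with NGG PAM and its nick position.

    ``protospacer_start`` and ``nick`` are always working-strand
    indices; for reverse-strand sites ``spacer``/``pam`` are given in
    the protospacer (reverse-strand) sense and the nick index is the
    working-strand position of the cut on the protospacer strand.
    """

    spacer: str
    pam: str
    strand: str  # '+' or '-'
    protospacer_start: int
    nick: int

    def __post_init__(self) -> None:
        if len(self.spacer) != PROTOSPACER_LEN:
            raise ValueError("spacer must be 20 nt")
        if self.pam[1:3] != "GG":
            raise ValueError(f"PAM {self.pam!r} is not NGG")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def protospacer_interval(self) -> tuple[int, int]:
        return self.protospacer_start, self.protospacer_start + PROTOSPACER_LEN

    def site_23mer(self) -> str:
        """Protospacer+PAM in protospacer sense (for re-cut checks)."""
        return self.spacer + self.pam


@dataclass(frozen=True)
class GuidePair:
    """ups-sgRNA / ext-pegRNA cis pair; ``dcn = ext.nick - ups.nick``."""

    ups: GuideSite
    ext: GuideSite
    dcn: int

    def __post_init__(self) -> None:
        if self.ups.strand != self.ext.strand:
            raise ValueError("cis pair requires both guides on one strand")
        if self.dcn != self.ext.nick - self.ups.nick:
            raise ValueError("dcn must equal ext.nick - ups.nick")
        if self.dcn <= 0:
            raise ValueError("ext nick must lie downstream of ups nick")


def find_guide_sites(locus: Locus, strand: str = "both") -> list[GuideSite]:
    """Exhaustively enumerate NGG guide sites on the requested strand(s).

    Forward sites: 20-nt protospacer at ``[s, s+20)`` immediately
    followed by NGG; nick at ``s+17``.  Reverse sites are protospacers
    on the complementary strand (working-strand motif CCN + 20 nt),
    reported with working-strand coordinates: the reverse-strand nick
    falls between working indices ``p+5`` and ``p+6`` for a CC at
    ``[p, p+2)``, i.e. nick index ``p+6``.
    """
    seq = locus.sequence
    n = len(seq)
    sites: list[GuideSite] = []
    if n < PROTOSPACER_LEN + PAM_LEN:
        logger.warning("locus %s shorter than 23 nt; no guide sites", locus.name)
        return sites
    if strand in ("forward", "+"):
        strands = "+"
    elif strand in ("reverse", "-"):
        strands = "-"
    elif strand == "both":
        strands = "+-"
    else:
        raise ValueError(f"unknown strand selector {strand!r}")

    if "+" in strands:
        for s in range(0, n - 23 + 1):
            if seq[s + 21 : s + 23] == "GG":
                sites.append(
                    GuideSite(
                        spacer=seq[s : s + 20],
                        pam=seq[s + 20 : s + 23],
                        strand="+",
                        protospacer_start=s,
                        nick=s + CUT_OFFSET,
                    )
                )
    if "-" in strands:
        for p in range(0, n - 23 + 1):
            if seq[p : p + 2] == "CC":
                block = seq[p : p + 23]
                sites.append(
                    GuideSite(
                        spacer=revcomp(block[3:]),
                        pam=revcomp(block[:3]),
                        strand="-",
                        protospacer_start=p + 3,
                        nick=p + 6,
                    )
                )
    sites.sort(key=lambda g: (g.nick, g.strand))
    return sites


def pair_guides(
    sites: list[GuideSite],
    edit: EditSpec,
    dcn_window: tuple[int, int] = DCN_WINDOW_DEFAULT,
    dcn_hard_min: int = DCN_HARD_MIN,
) -> list[GuidePair]:
    """Assemble valid ups/ext cis-nick pairs around an edit.

    All sites must share one strand and be given in the frame where
    that strand reads 5'->3' left to right (for reverse-strand designs
    run the search on the reverse-complemented locus).  Constraints:

    * ``ups.nick < ext.nick`` and ``dcn >= dcn_hard_min``;
    * ``dcn`` within ``dcn_window``;
    * every edit atom starts at or downstream of the ups nick (atoms
      may extend past the ext nick: both-sides edits).
    """
    if not sites:
        return []
    strands = {g.strand for g in sites}
    if len(strands) > 1:
        raise ValueError("pair_guides requires sites on a single strand")
    edit_start = edit.start
    ups_candidates = [g for g in sites if g.nick <= edit_start]
    if not ups_candidates:
        raise GeometryError(
            "uneditable geometry: edit starts at "
            f"{edit_start}, upstream of every candidate ups nick "
            f"(nicks: {sorted(g.nick for g in sites)})"
        )
    lo, hi = dcn_window
    lo = max(lo, dcn_hard_min)
    pairs: list[GuidePair] = []
    near_misses: set[int] = set()
    for ups in ups_candidates:
        for ext in sites:
            dcn = ext.nick - ups.nick
            if dcn <= 0:
                continue
            if dcn < dcn_hard_min:
                continue
            if lo <= dcn <= hi:
                pairs.append(GuidePair(ups=ups, ext=ext, dcn=dcn))
            else:
                near_misses.add(dcn)
    if not pairs and near_misses:
        nearest = sorted(near_misses, key=lambda d: min(abs(d - lo), abs(d - hi)))
        logger.warning(
            "no cis-nick pair with DCN in [%d,%d]; nearest achievable DCNs: %s",
            lo, hi, nearest[:5],
        )
    pairs.sort(key=lambda p: (abs(p.dcn - (lo + hi) // 2), p.ups.nick, p.ext.nick))
    return pairs


def find_helper_sites(
    sites: list[GuideSite],
    pair: GuidePair,
    min_separation: int = 25,
) -> list[GuideSite]:
    """Helper-gRNA candidates in the middle region between the two nicks.

    A helper nick must keep ``min_separation`` nt from both the ups and
    the ext nick (mirroring the DCN steric floor); candidates are sorted
    by distance from the inter-nick midpoint, closest first.
    """
    lo = pair.ups.nick + min_separation
    hi = pair.ext.nick - min_separation
    mid = (pair.ups.nick + pair.ext.nick) / 2
    cands = [
        g for g in sites
        if g.strand == pair.ups.strand and lo <= g.nick <= hi
    ]
    cands.sort(key=lambda g: (abs(g.nick - mid), g.nick))
    return cands


def write_sites_bed(sites: list[GuideSite], locus: Locus, path: str) -> None:
    """BED6 of protospacers plus zero-width nick features."""
    off = locus.origin_offset
    with open(path, "w") as fh:
        for i, g in enumerate(sites):
            s, e = g.protospacer_interval
            fh.write(
                f"{locus.name}\t{s + off}\t{e + off}\t"
                f"protospacer_{i}\t0\t{g.strand}\n"
            )
            fh.write(
                f"{locus.name}\t{g.nick + off}\t{g.nick + off}\t"
                f"nick_{i}\t0\t{g.strand}\n"
            )


def write_pairs_tsv(pairs: list[GuidePair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ups_nick\text_nick\tdcn\tstrand\tups_spacer\text_spacer\n")
        for p in pairs:
            fh.write(
                f"{p.ups.nick}\t{p.ext.nick}\t{p.dcn}\t{p.ups.strand}\t"
                f"{p.ups.spacer}\t{p.ext.spacer}\n"
            )
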