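"""End-to-end design orchestration: search -> build -> score -> validate.

For a reverse-strand design the whole problem is mirror-symmetric, so
the pipeline reverse-complements the locus, maps the edit into that
frame, runs the forward machinery, and notes the strand on the
resulting designs (coordinates in a reported design are then in the
mirror frame; the predicted working-strand allele is recovered by
reverse-complementing).  With ``strand="auto"`` the strand offering
more valid cis-nick pairs is chosen, matching the fact that the
method only needs PAMs on one strand.
"""

from __future__ import annotations

import logging
from dataclasses import replace

from .config import RunConfig
from .construct_builder import (
    MismatchInfeasibleError,
    assemble_ext_pegrna,
    build_es,
    build_hs,
    build_pbs,
    build_sgrna,
    es_end_for,
    introduce_mismatches,
    max_feasible_mismatches,
    retained_flanks,
)
from .design_scoring import (
    MISMATCH_K_REDUCED,
    ExpertDesign,
    attach_score,
    rank_designs,
)
from .edit_simulator import validate_design
from .guide_search import (
    GeometryError,
    find_guide_sites,
    find_helper_sites,
    pair_guides,
)
from .sequence_core import EditSpec, Locus, rc_edit, revcomp

logger = logging.getLogger(__name__)


def _forward_designs(
    locus: Locus, edit: EditSpec, cfg: RunConfig, strand_label: str
) -> list[ExpertDesign]:
    sites = find_guide_sites(locus, "forward")
    try:
        pairs = pair_guides(
            sites, edit, dcn_window=cfg.dcn_window, dcn_hard_min=cfg.dcn_hard_min
        )
    except GeometryError:
        return []
    designs: list[ExpertDesign] = []
    for pair in pairs:
        u, x = pair.ups.nick, pair.ext.nick
        es_end = es_end_for(edit, x)
        if u < cfg.pbs_len or es_end + cfg.hs_len > len(locus):
            continue
        try:
            es = build_es(locus, edit, u, x)
        except Exception:
            continue
        pbs = build_pbs(locus, u, cfg.pbs_len)
        hs = build_hs(locus, es_end, cfg.hs_len)
        flags_extra: tuple[str, ...] = ()
        if cfg.mismatch_scheme == "none" or cfg.mismatch_k == 0:
            es_mm, plan = introduce_mismatches(es, edit, u, x, scheme="none", k=0)
        else:
            try:
                es_mm, plan = introduce_mismatches(
                    es, edit, u, x,
                    scheme=cfg.mismatch_scheme, k=cfg.mismatch_k,
                    side=cfg.mismatch_side,
                )
            except MismatchInfeasibleError:
                side, max_k = max_feasible_mismatches(
                    edit, u, x, cfg.mismatch_scheme, cfg.mismatch_side
                )
                if max_k == 0:
                    es_mm, plan = introduce_mismatches(es, edit, u, x, "none", 0)
                else:
                    es_mm, plan = introduce_mismatches(
                        es, edit, u, x,
                        scheme=cfg.mismatch_scheme, k=max_k, side=side,
                    )
                    flags_extra = (MISMATCH_K_REDUCED,)
                    logger.info(
                        "mismatch k reduced from %d to max feasible %d (%s)",
                        cfg.mismatch_k, max_k, side,
                    )
        peg = assemble_ext_pegrna(pair.ext.spacer, cfg.scaffold, es_mm, hs, pbs, plan)
        helper = None
        helper_sgrna = None
        if cfg.helper in ("auto", "on"):
            want = cfg.helper == "on" or len(es_mm) >= 70
            if want:
                cands = find_helper_sites(sites, pair, cfg.helper_min_separation)
                if cands:
                    helper = cands[0]
                    helper_sgrna = build_sgrna(helper.spacer, cfg.scaffold, cfg.u6_g)
                elif cfg.helper == "on":
                    logger.warning(
                        "helper requested but no room between nicks %d and %d; omitted",
                        u, x,
                    )
        (f5s, f5e), (f3s, f3e) = retained_flanks(edit, u, x)
        d = ExpertDesign(
            pair=pair,
            ext_pegrna=peg,
            ups_sgrna=build_sgrna(pair.ups.spacer, cfg.scaffold, cfg.u6_g),
            edit=edit,
            es_end=es_end,
            strand=strand_label,
            helper=helper,
            helper_sgrna=helper_sgrna,
            edit_nick_distance_3p=f3e - f3s,
            edit_nick_distance_5p=f5e - f5s,
            flags=flags_extra,
        )
        report = validate_design(locus, d)
        if not report.ok:
            logger.warning(
                "design at nicks (%d,%d) failed validation: %s", u, x, report.message
            )
            continue
        d = replace(d, predicted_allele=report.trace.predicted_allele)
        d = attach_score(d)
        designs.append(d)
    return designs


def design_edits(
    locus: Locus, edit: EditSpec, cfg: RunConfig | None = None
) -> tuple[list[ExpertDesign], Locus]:
    """Produce ranked, validated designs for an edit.

    Returns ``(designs, frame_locus)`` where ``frame_locus`` is the
    locus in the coordinate frame the designs use (the reverse
    complement when a reverse-strand design was selected; its name is
    suffixed ``|rc``).
    """
    cfg = cfg or RunConfig()
    edit.check_bounds(locus)
    rc_locus = Locus(
        name=locus.name + "|rc",
        sequence=revcomp(locus.sequence),
        origin_offset=locus.origin_offset,
    )
    frames: list[tuple[str, Locus, EditSpec]] = []
    if cfg.strand in ("auto", "+"):
        frames.append(("+", locus, edit))
    if cfg.strand in ("auto", "-"):
        frames.append(("-", rc_locus, rc_edit(edit, len(locus))))

    best: list[ExpertDesign] = []
    best_frame = locus
    for strand_label, frame_locus, frame_edit in frames:
        ds = _forward_designs(frame_locus, frame_edit, cfg, strand_label)
        if len(ds) > len(best):
            best, best_frame = ds, frame_locus
    if best and best[0].strand == "-":
        logger.info("auto-selected reverse strand (%d valid designs)", len(best))
    return rank_designs(best)[: cfg.max_designs], best_frame


def working_strand_allele(d: ExpertDesign) -> str:
    """Predicted allele in the orientation of the input locus."""
    return d.predicted_allele if d.strand == "+" else revcomp(d.predicted_allele)
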