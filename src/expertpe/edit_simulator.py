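"""Mechanistic replay of the dual cis-nick editing pathway.

The simulator walks the idealized intended pathway step by step —
nick, excise, prime, reverse-transcribe, anneal, ligate — and
produces the predicted product allele.  It deliberately models only
the intended pathway: indel byproducts, flap-equilibrium kinetics and
mismatch repair are quantified empirically by the read classifier,
not simulated.

Because the ES/HS/PBS are derived from the locus by independent code
paths, a successful replay is a strong internal consistency check: the
genomic primer must equal the reverse complement of the PBS and the HS
must anneal exactly downstream of the edit.  The predicted allele must
coincide with direct string surgery (``apply_edit`` plus the mismatch
overlay); :func:`validate_design` asserts exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .construct_builder import edit_with_mismatches
from .design_scoring import ExpertDesign
from .sequence_core import Locus, apply_edit, revcomp


class SimulationError(ValueError):
    """Construct/locus inconsistency detected during pathway replay."""

    def __init__(self, step: str, message: str):
        self.step = step
        super().__init__(f"[{step}] {message}")


@dataclass
class SimulationTrace:
    excised_fragment: str
    primer: str
    synthesized: str
    predicted_allele: str
    steps: tuple[str, ...] = ()


def simulate_pe(locus: Locus, d: ExpertDesign) -> SimulationTrace:
    """Replay the editing pathway for one design; returns the trace.

    Steps: (1) nick at the ups and ext positions (and the helper, if
    present) on the working strand; (2) excise the inter-nick
    fragment; (3) verify the genomic primer against the PBS; (4)
    extend the primer with the reverse-transcribed extension (ES+HS);
    (5) anneal the HS downstream of the edit — exact match required;
    (6) ligate.
    """
    seq = locus.sequence
    u, x = d.pair.ups.nick, d.pair.ext.nick
    peg = d.ext_pegrna
    steps = [f"nick working strand at ups={u} and ext={x} (DCN {d.dcn})"]
    if d.helper is not None:
        steps.append(f"helper nick at {d.helper.nick} (promotes strand detachment)")

    excised = seq[u:x]
    steps.append(f"excise inter-nick fragment [{u},{x}) ({len(excised)} nt)")

    primer = seq[u - len(peg.pbs) : u]
    if revcomp(peg.pbs) != primer:
        raise SimulationError(
            "prime",
            f"genomic primer {primer} does not pair with PBS "
            f"(expected {revcomp(peg.pbs)})",
        )
    steps.append(f"PBS anneals to genomic 3' end {primer} (upstream binding)")

    synthesized = revcomp(peg.rtt)
    assert synthesized == peg.es + peg.hs
    steps.append(
        f"reverse transcription writes {len(synthesized)} nt "
        f"(ES {len(peg.es)} nt + HS {len(peg.hs)} nt)"
    )

    hs_target = seq[d.es_end : d.es_end + len(peg.hs)]
    if peg.hs != hs_target:
        raise SimulationError(
            "anneal",
            f"HS {peg.hs} does not match genome at [{d.es_end},"
            f"{d.es_end + len(peg.hs)}) ({hs_target})",
        )
    steps.append(f"3' flap anneals via HS at [{d.es_end},{d.es_end + len(peg.hs)})")

    allele = seq[:u] + peg.es + seq[d.es_end :]
    steps.append(f"ligate: predicted allele of {len(allele)} nt")
    return SimulationTrace(
        excised_fragment=excised,
        primer=primer,
        synthesized=synthesized,
        predicted_allele=allele,
        steps=tuple(steps),
    )


@dataclass
class ValidationReport:
    ok: bool
    step_failed: str | None = None
    message: str = ""
    trace: SimulationTrace | None = None
    expected_allele: str = ""

    def __bool__(self) -> bool:
        return self.ok


def expected_allele(locus: Locus, d: ExpertDesign) -> str:
    """Independent oracle: string surgery plus the mismatch overlay."""
    combined = edit_with_mismatches(
        d.edit, d.ext_pegrna.mismatch_plan, locus.sequence
    )
    return apply_edit(locus, combined)


def validate_design(locus: Locus, d: ExpertDesign) -> ValidationReport:
    """Run the simulator and compare against the string-surgery oracle."""
    want = expected_allele(locus, d)
    try:
        trace = simulate_pe(locus, d)
    except SimulationError as exc:
        return ValidationReport(
            ok=False, step_failed=exc.step, message=str(exc), expected_allele=want
        )
    if trace.predicted_allele != want:
        return ValidationReport(
            ok=False,
            step_failed="compare",
            message="simulated allele differs from edit-surgery oracle",
            trace=trace,
            expected_allele=want,
        )
    return ValidationReport(ok=True, trace=trace, expected_allele=want)
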