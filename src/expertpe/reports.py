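"""Design-report writers: TSV table, construct FASTA, annotated GenBank."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .design_scoring import ExpertDesign


def designs_table(designs: list[ExpertDesign]) -> pd.DataFrame:
    rows = []
    for rank, d in enumerate(designs, start=1):
        plan = d.ext_pegrna.mismatch_plan
        rows.append(
            {
                "rank": rank,
                "score": d.score,
                "flags": ";".join(d.flags) or ".",
                "strand": d.strand,
                "dcn": d.dcn,
                "ups_nick": d.pair.ups.nick,
                "ext_nick": d.pair.ext.nick,
                "pbs_len": d.pbs_len,
                "hs_len": d.hs_len,
                "es_len": len(d.ext_pegrna.es),
                "mismatch_scheme": plan.scheme,
                "mismatch_k": plan.count,
                "mismatch_side": plan.side if plan.count else ".",
                "helper_nick": d.helper.nick if d.helper else ".",
                "editor": d.editor_label,
                "ups_sgrna": d.ups_sgrna,
                "ext_pegrna": d.ext_pegrna.full,
                "helper_sgrna": d.helper_sgrna or ".",
                "predicted_allele": d.predicted_allele,
            }
        )
    return pd.DataFrame(rows)


def write_designs_tsv(designs: list[ExpertDesign], path: str) -> None:
    designs_table(designs).to_csv(path, sep="\t", index=False)


def write_constructs_fasta(
    designs: list[ExpertDesign], path: str, rna: bool = False
) -> None:
    with open(path, "w") as fh:
        for rank, d in enumerate(designs, start=1):
            peg = d.ext_pegrna.as_rna() if rna else d.ext_pegrna.full
            ups = d.ups_sgrna.replace("T", "U") if rna else d.ups_sgrna
            fh.write(f">design{rank}_ext_pegRNA dcn={d.dcn}\n{peg}\n")
            fh.write(f">design{rank}_ups_sgRNA\n{ups}\n")
            if d.helper_sgrna:
                helper = d.helper_sgrna.replace("T", "U") if rna else d.helper_sgrna
                fh.write(f">design{rank}_helper_sgRNA\n{helper}\n")


def write_construct_genbank(d: ExpertDesign, path: str) -> None:
    """Annotated GenBank of the ext-pegRNA encoded construct."""
    peg = d.ext_pegrna
    rec = SeqRecord(
        Seq(peg.full),
        id="ext_pegRNA",
        name="ext_pegRNA",
        description=f"dual cis-nick design, DCN {d.dcn}",
        annotations={"molecule_type": "DNA"},
    )
    pos = 0

    def feat(length: int, label: str, ftype: str = "misc_feature") -> None:
        nonlocal pos
        rec.features.append(
            SeqFeature(
                FeatureLocation(pos, pos + length),
                type=ftype,
                qualifiers={"label": [label]},
            )
        )
        pos += length

    feat(len(peg.spacer), "spacer")
    feat(len(peg.scaffold), "scaffold")
    rtt_start = pos
    feat(len(peg.hs), "HS (revcomp)")
    feat(len(peg.es), "ES (revcomp)")
    rec.features.append(
        SeqFeature(
            FeatureLocation(rtt_start, pos),
            type="misc_feature",
            qualifiers={"label": ["RTT"]},
        )
    )
    feat(len(peg.pbs), "PBS")
    plan = peg.mismatch_plan
    if plan.count:
        rec.features.append(
            SeqFeature(
                FeatureLocation(rtt_start, rtt_start + len(peg.hs) + len(peg.es)),
                type="variation",
                qualifiers={
                    "label": [
                        f"{plan.count} {plan.scheme} mismatches ({plan.side}); "
                        f"ref positions {list(plan.positions)}"
                    ]
                },
            )
        )
    SeqIO.write(rec, path, "genbank")
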