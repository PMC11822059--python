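# Methods

## The editing model

`expertpe` models prime editing with two *cis* nicks. An SpCas9 H840A
nickase–reverse-transcriptase fusion is directed by two guides to the
same strand of a local target region (the "working strand", the one
carrying both protospacers): the ups-sgRNA nick at index *u* and the
ext-pegRNA nick at index *x* > *u*, both placed 3 nt 5′ of their NGG
PAMs (between protospacer positions 17 and 18 — fixed, standard SpCas9
behavior). The single-stranded fragment `[u, x)` between the nicks
detaches; the genomic 3′ end at *u* anneals to the primer binding site
(PBS) of the ext-pegRNA 3′ extension ("upstream binding") and is
extended by the reverse transcriptase along the RT template, which
consists of an edit sequence (ES) and a homologous sequence (HS). The
new 3′ flap anneals via the HS downstream of the edit and ligation
yields the product allele.

The simulator (`edit_simulator`) replays exactly this intended
pathway and nothing else: indel byproducts, flap-equilibrium kinetics,
and mismatch repair are not modeled — they are what the read
quantifier measures empirically. The simulator's value is as an
internal oracle: because ES, HS and PBS are derived from the locus by
independent code paths, replay success requires the genomic primer to
equal rc(PBS) and the HS to anneal exactly, and the replayed allele
must equal direct string surgery (`apply_edit` plus the mismatch
overlay). Every design the pipeline emits has passed this check.

## Coordinates and edit algebra

All coordinates are 0-based, half-open, on the working strand. Edits
are ordered, non-overlapping atoms (interval → payload); deletion =
empty payload, insertion = empty interval, replacement = both
non-empty. The field convention of nick-relative labels has no
position 0: −1|+1 straddle the nick, so "−37to−1" at nick *n* maps to
`[n−37, n)`. Reverse-strand designs are handled by mirror-frame
reduction: the locus is reverse-complemented, the edit mapped into
that frame, and the forward machinery reused; with `strand: auto` the
strand offering more valid pairs wins.

## Tunable parameters

| parameter | default | range | rationale |
|---|---|---|---|
| DCN window | 32–40 nt | relaxed 25–71, permissive 25–96 | editing peaks at 32–40 nt at endogenous loci; reporter signal is robust to 71 nt and detectable to 96 nt |
| DCN hard floor | 25 nt | — | nicks ≤ 24 nt apart nearly abolish editing, consistent with steric clash of adjacent nickases; never relaxable |
| PBS length | 12 nt | effective 9–16 | 12 nt maximized efficiency at both tested loci; < 9 nt collapses editing (warning) |
| HS length | 16 nt | tested 12–22 | ≥ 16 nt strongly enriches for efficient designs; < 16 nt warns |
| mismatch scheme / k | consecutive, 11 | 0–17; every3/every5 | efficiency rises with mismatch count and peaks at 10–11; interval spacings perform comparably |
| helper trigger | ES ≥ 70 nt | `auto`/`on`/`off` | a third cis nick midway between the pair roughly tripled efficiency for ≥ 71-bp replacements |
| helper min separation | 25 nt | — | mirrors the DCN steric floor; untested below that, so conservatively equal |
| quant window margin w | 10 nt | — | window `[u−w, es_end+w]` around the rewritten region |

DCN is defined nick-index minus nick-index; the hard floor of 25
implements "24 or shorter is avoided" under that convention. The
score aggregates DCN/PBS/HS credits in equal thirds — the underlying
evidence is ordinal, so the weights are declared heuristic and live in
config. Everything else is a non-numeric flag (mismatch recommended
when a retained flank ≥ 14 nt exists without mismatches; helper
recommended for ES ≥ 70 nt; caution for net insertions > 50 bp; TTTT
pol III terminator runs; re-cut potential when the product retains an
intact protospacer+PAM). Ranking ties break by DCN distance from 36
(the optimal-window midpoint), then ext-nick position.

## Mismatch engineering

The retained (genome-identical) parts of the ES can re-hybridize with
the genomic flaps and stall reverse transcription. The engine
substitutes *k* positions of the designated retained flank via the
fixed transversion map A→C, C→A, G→T, T→G — deterministic,
reproducible, and maximally destabilizing for the flap duplex; the
exact published base choices are not recoverable, so a fixed map was
chosen over a sampled one. Positions start at the nick-adjacent flap
terminus (position `x−1` going left for the 3′-flap side, `u` going
right for the 5′-flap side) and are spaced every 1/3/5 bases;
`side: auto` picks the longer retained flank. Mismatches never fall in
edit payloads or the HS, and the predicted allele includes them — the
"intended edit" is defined as the mismatched product, and the read
classifier checks those positions accordingly. When the configured
*k* is infeasible the pipeline clamps to the largest feasible value
and flags `MISMATCH_K_REDUCED` (the library call instead raises,
reporting the maximum).

## Read classification

`align_global` is a Needleman–Wunsch aligner (match +1, mismatch −1,
linear gap −2) with a fixed traceback priority
(match/mismatch > gap-in-read > gap-in-allele), jit-compiled for
throughput. A linear gap penalty was chosen over affine because it is
fully specifiable and adequate for short amplicons; the scheme is
configurable. Reads shorter than the quantification window span are
`unassigned` (global-alignment end-gap placement is ambiguous for
truncated reads, so spanning is decided by length, which is
deterministic). Otherwise the read is aligned to both alleles, the
higher score wins (ties to the edited allele), any gap inside the
window makes it `indel`, and gap-free reads are `intended`/`unedited`
when they match the winning allele at every edited position, else
`substituted`. Substitution-only reads count toward neither intended
nor indels, matching the partition used by the two read-count
formulas (desired/total and indel-containing/total). No parity with
CRISPResso2's exact windowing is attempted.

## Synthetic data

`make_locus` draws a background free of GG/CC dinucleotides, so the
only NGG guide sites are the planted protospacer+AGG blocks
(junction-guarded; an internal re-scan asserts the realized site set
equals the plan). This is deliberately cleaner than genomic sequence:
real loci carry additional PAMs, so guide search on real data returns
more candidates and relies on the geometric filters rather than
uniqueness. `simulate_reads` emits full-length amplicon reads in the
planted classes — edited allele, reference, reference with a 1–10-nt
indel at a randomly chosen nick (where real byproducts arise), and
substitution-only reads — with class counts allocated by largest
remainder (exact, making golden tests deterministic) or multinomially,
plus optional uniform per-base substitution errors. It does not model
sequencer-specific error profiles, quality decay, or paired-end
structure; passing tests therefore demonstrate the classifier's
correctness on its stated decision rules, not robustness to real
instrument noise.

The quantifier's statistical check plants 30%/5%/65%
intended/indel/unedited at n = 1000 and error rate 0.001, and requires
per-seed recovery within 3 binomial standard errors over 20 fixed
seeds. The fixture edit for that check is a compact 6-bp replacement:
sequencing errors landing on checked edit positions legitimately
reclassify reads (intended→substituted, unedited→substituted), so the
size of the checked region sets a known recovery bias (~0.1% per
checked position per class at this error rate); a compact edit keeps
that bias an order of magnitude below the binomial bound, which is
what makes "recovery of planted values" the right null. The exactness
check uses the flagship 37-bp full inter-nick replacement with
error-free deterministic allocation.

## Problem sizes and numerical choices

Test and acceptance sweeps use loci of 400–450 nt with nicks around
position 150–180, 500 random design cases for the simulator-oracle
sweep (DCN 25–96, deletions 1–88 bp, replacements to 88 bp,
insertions to 100 bp, compound both-sides edits), 200 random pairs of
length ≤ 8 for the aligner-vs-enumeration sweep, and read sets of
1000. These sizes exercise every code path at amplicon-realistic
scale. Fold changes round half-up (decimal arithmetic, not binary
float) to the reported digits; product purity with zero indel reads is
reported as an infinity marker, serialized as the string `"inf"`.

## Known limitations

- Only NGG PAMs and the 17/18 cut geometry; no Cas12a or non-NGG
  variants, no genome-wide off-target search.
- The DCN optimum derives from two endogenous loci and one reporter;
  it is a default, not ground truth, hence the window presets.
- Whether published insertion-type designs placed their extra
  mismatches inside the inserted payload or the retained flank is
  ambiguous; the engine defaults to the retained flank (payloads are
  never mutated) and records the plan so users can audit.
- Efficiency *prediction* is out of scope: the score ranks designs by
  geometric compliance and cannot anticipate chromatin context or
  locus-specific repair outcomes.
- The scaffold is the standard SpCas9 sgRNA scaffold and is
  config-overridable; the TTTT terminator scan covers spacer and
  extension but deliberately exempts the scaffold, which contains a
  TTTT of its own.
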