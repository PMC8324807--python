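# Methods

## The screen being modeled

A base editing-coupled survival screen couples a cytosine base editor's
PAM-dependent activity to cell survival. The construct places a randomized
PAM slot (NNNN, 256 sequences) upstream of a counterselectable *upp* variant
whose sixth codon is TGG. Editing converts the TGG codon into one of the
three stop codons reachable by C·G→T·A conversion — TAG, TGA or TAA (the
two Gs of TGG are Cs on the antisense strand) — truncating Upp and making
the cell 5-fluorouracil resistant. Rounds of induction plus 5-Fu selection
enrich lineages with editable PAMs; deep sequencing of the ~152-bp amplicon
spanning the PAM slot and the target codon quantifies the outcome. besskit
implements the quantitative side of this design end to end: construct
model, read simulation, read classification, statistics, population
dynamics and reporting.

## Amplicon model

`AmpliconTemplate` holds the layout as 0-based half-open coordinates: a
constant 5' anchor (≥8 nt, 20 nt in the default), the PAM slot, and a
constant 3' region that contains the target codon at a fixed offset. All
classification logic depends only on these coordinates, never on the
literal bases, so any user template with the same shape works. The packaged
default is a synthetic 152-bp template (20-nt anchor, 4-nt PAM slot, 6-nt
linker, then a short open reading frame with TGG as codon 6); it stands in
for the real construct, whose exact sequence is not needed for any
statistic. PAMs are reported in the orientation in which the canonical
motif reads NGG; the template records whether that requires reverse
complementing the sequenced slot (`pam_report_strand`, default
`as_template`).

Codon states are exactly {TGG, TAG, TGA, TAA, OTHER}. OTHER (any other
3-mer, including Ns) is counted in denominators but never as edited: only
genuine stop conversions at the target codon score as editing.

## Synthetic reads

`generate_library_reads` draws each read's PAM from normalized library
weights and its codon state from a per-PAM edited fraction; edited outcomes
split TGA/TAG/TAA as 0.5/0.2/0.3 by default. That split is a configurable
modeling choice: the screen's characteristic outcome ordering is TGA most
frequent, then TAA, then TAG, and the default preserves the ordering while
the magnitudes are explicitly invented. Reads are emitted on either strand
(probability 0.5) and corrupted by a substitution/N/adapter error model.
Defaults: 0.2% substitutions, 0.05% Ns, 1% adapter read-through tails,
Phred 37 for correct bases and Phred 10 for error bases — an idealization
of cleaned short-read amplicon data. The generator returns a `TruthTable`
of realized per-read genotypes, which is what every round-trip test and the
acceptance script compare against.

What the generator does **not** emulate: PCR amplification bias, indels,
position-dependent quality profiles, chimeric reads, or miscalls at high
reported quality. Passing round-trip tests therefore demonstrate pipeline
correctness under the stated error model, not robustness to every artifact
of a real sequencing run; the cleaning thresholds and anchor tolerance are
exposed so real data can be handled more conservatively.

## Read processing

Cleaning: 3' adapter removal (leftmost match of a ≥10-base adapter prefix
with ≤1 mismatch), then rejection of reads with >10% N, mean Phred < 20, or
insufficient post-trim length. The published processing for this screen
names these operations without parameters; the defaults here are the
conventional ones and all are configurable.

Anchoring: the locator scans the read and its reverse complement for the
template's 5' anchor and for the constant linker between PAM slot and
codon, each allowing at most 2 substitutions (no indels — negligible for
short amplicons and it keeps the search exactly checkable). The search
splits the anchor into `max_mm + 1` chunks so any valid placement contains
at least one exact chunk (pigeonhole); exact chunk hits generate candidate
offsets that are then scored by full Hamming distance. This is provably
equivalent to an exhaustive sliding-window scan, and the test suite holds
it to that standard count-for-count against an independently written
brute-force reference. Ties for best placement are rejected as ambiguous —
the pipeline never guesses a PAM.

Base-quality masking: extracted PAM and codon bases with Phred < 20 are
masked to N before classification; an N in the PAM rejects the read, an N
in the codon classifies it OTHER. This is the standard amplicon-calling
defense against sequencing miscalls fabricating stop codons, and it
composes with the N-handling rules above. Its cost is a small downward bias
in efficiency estimates (a read whose codon contains a masked base drops
out of the numerator), about 0.75% relative at the default error rates —
negligible against the binomial sampling error at the depths used here.

Accounting is exact: reads_in = cleaned + cleaning rejections; cleaned =
classified + extraction rejections; every rejection carries a reason.

## Statistics

Efficiency, enrichment factor, functional (>1% efficiency, strict) and
enriched (EF > 1, strict) calls are as defined in the README. Design
choices:

- The EF numerator counts only *edited* reads of the PAM in the enriched
  library; an all-reads numerator is available behind a flag for
  sensitivity analysis.
- Denominators use classified reads (post-cleaning, post-anchoring); the
  choice is recorded in the output metadata.
- Library uniformity is operationalized as a chi-square goodness-of-fit
  against the uniform 1/4^k design plus the coefficient of variation of
  per-PAM frequencies — a 256-category library admits no meaningful
  univariate normality test.
- Replicates are merged by arithmetic mean with consensus calls
  (functional/enriched in all replicates); replicate tables must cover
  identical PAM sets.
- Reported fold values round half-away-from-zero to integers (9.26 → 9,
  55.2 → 55).
- Undefined values (efficiency with zero reads, EF with zero initial
  frequency) propagate as NaN and are never coerced to 0; undefined is
  never functional/enriched.

## Selection simulator

One round is induction → selection → renormalization/bottleneck:

1. unedited cells of PAM p convert to edited with probability π_p + μ;
2. edited abundance is multiplied by 1, unedited by s;
3. proportions are renormalized; stochastic mode then draws a multinomial
   bottleneck of N colonies.

Parameters, units and defaults: π_p (probability per induction round;
default 0 unless configured, with 0.1 the canonical-PAM anchor — roughly
one cell in ten survives 5-Fu after induction with an NGG PAM); s
(dimensionless per-round relative fitness of unedited cells under 5-Fu,
default 0.02, a single multiplicative factor absorbing killing and growth
differences — the screen's growth curves constrain its sign, not its
value); μ (per-round spontaneous *upp*-inactivation probability, default
1e-6, preventing degenerate zero-survivor states and modeling the escape
route that survival screens cannot distinguish from editing); N (colonies
per bottleneck, default 1e5, matching the ~1e5 clones harvested between
rounds). Deterministic mode propagates expected proportions exactly;
stochastic mode draws binomial conversions, binomial survival thinning and
the multinomial bottleneck.

No attempt is made to fit (π, s) so that simulated mixing trajectories
reproduce particular published colony percentages: the per-round odds
multipliers implied by different reported experiments are mutually
inconsistent under a single (π, s), so the simulator's claims are the
qualitative ones — monotone enrichment whenever π_f > π_i and s < 1, the
closed-form odds update, and stochastic/deterministic agreement — all of
which are tested.

## Visualization

Heatmap: rows are PAM bases 1–2, columns bases 3–4, both in A,C,G,T order;
values are efficiencies divided by the maximum (max cell exactly 1 when any
efficiency is positive); missing PAMs are zero with a mask flag. Logo:
weighted position frequencies with information content
IC_i = 2 + Σ f log₂ f bits (0·log 0 ≡ 0) and letter heights f·IC; logos are
EF-weighted by default with an unweighted option, since the choice of
weighting is genuinely open. Wheel: prefix tree with position 1 innermost;
each node's arc is its parent's arc split proportionally to summed EF
weight; angular conservation holds at every ring to 1e-9. Figures are
vector SVG with timestamps stripped and fixed hash salts, so reruns are
byte-identical; every matrix is also written as TSV, from which all figures
can be rebuilt.

## Pipeline, demo and problem sizes

The pipeline stages (simulate → process → stats → report) share one YAML
config and one output directory; each run writes its resolved config and a
SHA-256 manifest, and identical config + seed gives identical manifests.

The packaged demo is a 2-round, 256-PAM deterministic screen with 40 active
PAMs and 200 000 reads per library — deep enough that every PAM keeps
hundreds of reads in the initial library while one CPU processes it in
about a minute. The 16 NGGN PAMs get π spread over 0.08–0.12 (around the
canonical-PAM anchor), 24 further PAMs spread over 0.02–0.30, each PAM with
a distinct π so the efficiency ranking is well defined. The demo sets
μ = 0: it is a parameter-recovery experiment whose ground truth is "π > 0",
and background escape is a property of the assay (not of the editor) that
would plant edited mass in every inert lineage and make exact recovery of
the active set ill-posed. With escape enabled the same pipeline runs
unchanged; the functional call then includes escape-driven survivors, which
is the screen's real false-positive mode.

## Known limitations

- Single-end, full-length amplicon reads; no paired-end merging.
- Substitution/N errors only; no indel handling in reads or anchors.
- The selection model compresses growth kinetics into one per-round factor;
  it cannot resolve liquid-culture vs plate-colony dynamics within a round.
- Efficiency estimates carry the small masking bias described above;
  no shrinkage or multiple-testing correction is applied to per-PAM calls
  (the screen's definitions are plain thresholds).
- The default template is synthetic; analyses of real data must supply the
  construct's own template file.
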