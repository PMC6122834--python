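# Methods

## Scope and data model

`splicedm` analyses two-condition (mutant vs control) bulk RNA-seq with a
small number of biological replicates per condition. All coordinates are
0-based half-open internally; GTF input (1-based inclusive) is converted on
read. The unit of analysis is the *gene cluster*: all transcripts whose
exonic spans overlap on one strand. Clustering is strand-specific —
antisense overlaps never merge — which keeps the transcription-direction
definitions of donor/acceptor sides and first/last exons unambiguous.

Within a cluster, the exon boundaries of all transcripts partition the
exonic union into *exonic parts*, numbered 1..N in genomic order. Each
transcript corresponds to an ordered path of part indices, and a splicing
event is a pair of alternative paths (the variable parts plus the shared
flanking constitutive parts).

## Event enumeration

Events are found by diffing every unordered pair of transcript paths in a
cluster. Each maximal run of parts present in exactly one transcript,
bounded by shared parts (or a transcript end), is one candidate region,
classified by the local splice structure:

- **ES** — one path splices around internal part(s) the other includes,
  with both edges of the variable block spliced;
- **A5SS / A3SS** — the variable parts extend one flanking exon
  contiguously on its donor / acceptor side (sides defined in
  transcription direction, so the genomic left/right assignment flips with
  strand);
- **IR** — the variable parts join both flanks contiguously in one path
  (a single exon spanning the region) while the other path splices
  directly between the flanks;
- **ME** — each path contributes exactly one spliced variable block and
  the blocks do not interleave;
- **AFE / ALE** — a terminal region where each path has its own first
  (last) exon spliced to the first shared part.

Regions that fit none of these (for example a one-sided terminal
extension, which changes a transcription start rather than splicing) are
skipped with a logged warning, never a crash. Events are deduplicated by
(type, path1, path2); path1 is the lexicographically smaller index tuple,
a total order that reduces to "the path containing the lower smallest part
index" where those differ. The event id serializes cluster, chromosome,
strand, the variable-region span, gene id, type and both paths, and is
injective within an annotation.

The PSI *numerator path* is the longer path (summed part length) for
ES/A5SS/A3SS/ME/IR and the proximal terminal exon — smaller splice-site
distance to the nearest shared exon — for AFE/ALE. Ties default to path1
and are logged; they cannot arise in the bundled synthetic annotation.

## Read counting

Alignments come from SAM/BAM (via pysam) or a simplified block-interval
TSV. CIGAR M/=/X and D operations extend a match block; N splits blocks
(splice gaps). Only uniquely mapped reads are counted: multiplicity tag
equal to 1 when present, else mapping quality ≥ 255 (configurable). A read
increments every exonic part any block overlaps by ≥ 1 base; reads
touching parts of more than one cluster are discarded as ambiguous.
Junction counting requires exact coordinate match on both ends of a gap;
unannotated gaps go to a reported "unknown" sink. Event path support is
the sum of counts over the features *exclusive* to each path — parts and
junctions in one path but not the other; shared features are
uninformative and contribute to neither. Consequently the raw
path-1 read fraction is a feature-weighted proportion, not the molar
isoform fraction: a path exposing more exclusive features collects more
reads per transcript. PSI values are therefore comparable between
conditions (the contrast the test addresses), not across events.

## The Dirichlet-multinomial test

Replicate path counts (x₁, x₂) follow a two-category
Dirichlet-multinomial: the replicate-level proportion is
Beta(s·π, s·(1−π)), so P(x₁|n, π, s) has the beta-binomial Beta-function
closed form, evaluated via log-gamma. π is the population path-1
proportion; s > 0 is the precision, with intraclass correlation
ρ = 1/(s+1) (s → ∞ recovers the binomial/multinomial).

The null model shares π across conditions; the alternative gives each
condition its own π with a shared s. The LRT statistic 2(ℓ_alt − ℓ_null),
clamped at zero against numerical error, is referred to χ²(1) — sharing
the dispersion makes the proportion change the single tested parameter.

**Dispersion is estimated once, across events.** With two replicates per
condition, a precision re-estimated per event (four observations, plus
incidental proportion parameters) is strongly biased toward
under-dispersion, and Monte Carlo shows the resulting test rejects true
nulls at ~20% for a nominal 5%. The pipeline instead estimates a single
shared s by a method of moments on within-condition replicate scatter:
for replicate proportions p̂ⱼ = xⱼ/nⱼ within one event-condition group,
E[(p̂ⱼ−p̂ₖ)²/2] = π(1−π)·(ρ + (1−ρ)(1/nⱼ+1/nₖ)/2), which identifies ρ by a
ratio of sums across all groups; the plug-in π̂(1−π̂) is bias-corrected and
the solve iterated. The estimator is unaffected by true between-condition
differences (it never compares across conditions) and carries no
incidental-parameter bias. With s then held fixed, only the proportions
are profiled per event and the χ²(1) reference is calibrated (empirical
type-I error ≈ 0.047 at α = 0.05 over 2,000 simulated null events at the
default study conditions). Per-event free-precision maximum-likelihood
fits remain available (`fit_dm_null`/`fit_dm_alt` without `s_fixed`, and
`test_events(dispersion="per-event")`) for diagnostics; their optimizer
profiles s by a 49-point coarse scan over log s with bounded Brent
refinement, an inner bounded 1-D search for each proportion, and a
boundary check, and dominates a dense 200×200 (logit π, log s) grid.

Numerical choices: proportions guarded in (10⁻⁶, 1−10⁻⁶); s bounded in
[10⁻³, 10⁶]; proportion searches on the logit scale with absolute
tolerance 10⁻¹⁰; zero-depth replicates dropped (no information); an event
is testable only when every condition has ≥ 1 sample and replicate-summed
depth ≥ 10 (configurable) — untestable events are excluded and reported.

## Calling and reporting

p-values are BH-adjusted once, pooled across all seven event types
(q = min over the tail of p·m/rank). PSI per condition is the
alternative-model MLE mapped to the numerator path; ΔΨ = Ψ_mut − Ψ_ctrl;
log-odds use natural logs. An event is significant iff |ΔΨ| > 0.03 and
q < 0.25, both strict, and the *favored path* is the one gaining usage in
the mutant (sign of ΔΨ). Cross-mutant overlap intersects significant
event-id sets and refuses to compare runs whose annotation hashes differ.

Expression analysis is deliberately simple, mirroring a plain fold-change
screen rather than a variance-modelled DE test: RPKM =
count / (gene-length-kb × library-millions) with gene length the exonic
union over the gene's transcripts; condition means are arithmetic means of
per-sample RPKM; fold = mutant/control on means floored at 0.1 RPKM
(avoiding division blow-ups at negligible expression); up iff fold ≥ 2,
down iff fold ≤ 0.5, boundaries inclusive.

## Synthetic data

The generator emulates the study design: two conditions × two biological
replicates (both configurable). Per event and sample, depth n ~
Poisson(depth_mean) mimics uneven coverage; the replicate proportion is
Beta(s·π, s·(1−π)); x₁ ~ Binomial(n, p) — exactly the fitted model, so
recovery tests probe estimation, not model mismatch. Defaults: depth 100,
s = 20 (ρ ≈ 0.05, a visible but moderate replicate effect), base
proportion 0.5, ΔΨ = 0 (global or per-event). The toy annotation builds,
per requested event, a two-transcript gene realizing exactly one event of
each type with ~100-bp exons and randomized intergenic spacing; the read
simulator draws uniform fragment starts along a chosen isoform and emits
gapped, uniquely mapped single-end reads.

What the simulator does *not* emulate: sequence content and alignment
error, positional/GC coverage bias, paired-end structure, multi-gene
read sharing, and annotation incompleteness. Passing tests therefore
demonstrate the statistical machinery and the counting/enumeration logic
under the stated generative model, not robustness to real-library
artefacts. All generators run from one master seed with fixed substream
offsets; identical seeds give byte-identical outputs.

Problem sizes used by the checks — ~2,000 events for null calibration,
~500 for effect recovery, 700 for the two-mutant overlap study, read depth
10,000 for counting — were chosen as the smallest sizes at which the
Monte-Carlo standard errors are comfortably below the margins being
asserted.

## Known limitations

- Exactly two isoform paths per event; complex regions produce multiple
  pairwise events rather than one multi-path event, and unclassifiable
  regions are skipped.
- The shared-dispersion assumption (one s across events and conditions)
  trades per-event flexibility for calibration; strongly event-specific
  overdispersion would be mis-modelled.
- Reads are treated as independent single-end units (no fragment
  reconstruction or duplicate marking).
- PSI is feature-weighted (no effective-length correction), so absolute
  PSI levels are not comparable across events of different geometry.
- The 2-fold expression rule is a screen, not a test: no variance model,
  no significance statement.
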