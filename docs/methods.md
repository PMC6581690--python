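# Methods

This note documents the models, conventions and numerical choices behind
fgarray — what each stage computes, why the defaults are what they are,
and what the simulator does and does not emulate.

## Screening statistics

**Identity.** `best_identity` scores every ungapped register of the
probe along both strands of the subject, including partial overlaps at
the subject edges, and reports matches divided by the probe length. The
alignment is deliberately ungapped: the stretch and free-energy
statistics assume a fixed register, ungapped scans are exactly
reproducible, and an exact common substring of length k then guarantees
identity ≥ 100·k/L, which keeps the three statistics mutually
consistent. A gap-tolerant identity would only lower the apparent safety
margin of a probe, never raise it past the screen, because the criteria
are applied to the maximum over registers. Ties prefer the forward
strand, then the smaller subject offset.

**Stretch.** `longest_stretch` is the longest exact common substring
between the probe and either strand of the subject, computed with a
suffix automaton built once per subject string (cached), so screening
many candidates against the same pool is linear in probe length per
comparison. Long perfect stretches nucleate stable duplexes even when
overall identity is low, which is why stretch is screened independently
of identity.

**Free energy.** Duplex stability uses the unified oligonucleotide
nearest-neighbor ΔG°37 parameters (SantaLucia 1998), shipped as a TSV
(`fgarray/data/nn_unified_dg37.tsv`) and swappable via
`load_parameter_set`. For a probe aligned against a nontarget window,
mismatched positions contribute nothing and break stacking: ΔG is the
sum of stack terms inside matched runs of length ≥ 2, plus initiation
charged once (at the first base of the first run and the last base of
the last run); with no run of length ≥ 2 the window forms no stable
duplex and ΔG = 0. Tandem-mismatch and dangling-end parameters are
deliberately omitted — the thresholds this screen feeds were calibrated
against a coarse model of the same character, and a finer heteroduplex
model would change the scale the thresholds live on. No salt or
temperature correction is applied; thresholds are compared on the ΔG°37
scale. ΔG is evaluated at the best-identity register only (not the
ΔG-optimal register); this bounds cost and the best-identity register
dominates binding in an ungapped model, but it is an approximation and
is documented as such. Screening ΔG values are rounded to 10⁻⁶ kcal/mol
— far below the 0.01 kcal/mol table resolution — so strict threshold
comparisons are not decided by floating-point accumulation order.

**Criteria.** Nontarget side: identity < 90 % (the conservative end of
the published 90–92 % range), stretch < 20 bp, minimum ΔG > −35
kcal/mol. Group side (group-specific probes only, against every family
member): identity > 94 %, stretch > 35 bp, maximum ΔG < −60 kcal/mol.
All six are strict inequalities; a statistic landing exactly on a
threshold fails. Sequences sharing the probe's gene family are excluded
from the nontarget pool automatically; an empty pool passes vacuously
with a warning.

## Probe selection

Candidates are every window of 50 nt (configurable step), filtered by GC
content 30–70 %, homopolymer runs ≤ 6, and self-reverse-complement
stretch < 12 — standard long-oligo hygiene filters, all configurable.
Passing candidates are ranked by the **specificity margin**: the minimum
over criteria of the normalized distance from the threshold (e.g.
(90 − identity)/90), maximized, with ties broken by the leftmost start.
This picks probes far from every boundary rather than barely-passing
ones. Up to k = 2 probes per target are emitted by default (array real
estate vs redundancy; per-target multiplicity is a design convention,
not a derived quantity). Group-specific candidates are enumerated from
the longest family member (maximal candidate space) and positions are
reported on it.

Legacy probes are revalidated with two requirements: exact containment
(a full-length stretch) in at least one current target, and a pass of
the current nontarget screen. Valid probes exempt their targets from
redesign; targets covered only by invalid probes are returned for
recycling.

## PM/MM controls

An MM control is built from its PM probe by splitting the 50-mer into 5
equal segments and substituting one uniformly chosen position per
segment with a uniformly chosen different base — exactly 5 mismatches
(10 %), one per 10-nt segment, deterministic under a seed. No attempt is
made to avoid creating new stretches; that matches the simplest reading
of segment-wise random mismatching and keeps the construction unbiased.

## Array layout

Controls (negative, CORS, optionally 16S-positive and genome controls)
are instantiated per class — user-supplied sequences or random 50-mers —
and distributed round-robin so every subarray holds at least one
negative control (background estimation) and one CORS probe
(normalization); designed probes are distributed round-robin after a
seeded shuffle. MM controls are always placed on their PM mate's
subarray so PM/MM ratios compare nets against the same local background.

## Hybridization simulator

Expected specific signal of probe p under a mix:

    E[p] = gain · (GC_p/0.5)^γ · Σ_seq mass(seq) · yield(identity(p, seq))

with component masses split equally over their pool's sequences (equal
gene representation in a labeled extract), yield(100 %) = 1, yield
decaying geometrically at `crosshyb_decay` per identity point below 100
and clamped to 0 below an 85 % identity floor. Defaults: gain 2,000
intensity units/ng, γ = 4 (so a GC 0.37 probe reports roughly an order
of magnitude less than a GC 0.63 probe — the mechanism behind low-GC
organisms' lower hybridization sensitivity), decay 0.1^(1/10) so a
5-mismatch MM probe at 90 % identity yields exactly 10 % of its PM's
signal and PM/MM ratios cluster near 10. Observed intensity multiplies
E[p] by mean-1 lognormal spot noise (CV 0.1 default), adds Gaussian
background (mean 100, sd 25), optionally applies a per-array lognormal
scale factor (off by default; it is what CORS normalization removes),
clips at zero and saturates at 65,535 (16-bit scanner scale). Negative
controls receive background only; CORS probes receive a fixed 5,000-unit
spike independent of the mix. Everything is bit-reproducible under a
seed.

Cross-hybridization is driven by best ungapped identity alone — not
stretch or ΔG — because no quantitative cross-hybridization yield curve
is available to fit; the curve is a declared stand-in with the right
qualitative shape (negligible signal below ~90 % identity), and
downstream tests only rely on properties robust to its exact form. The
simulator has no spatial artifacts, gridding error, dye chemistry or
two-color ratio structure; passing tests therefore demonstrate the
correctness of the analysis chain under the stated generative model, not
robustness to scanner pathologies.

**Synthetic pools.** `make_synthetic_pools` builds each gene family from
a random ancestor drawn with exact GC composition (so realized pool GC
tracks the request within ±0.03 by construction); members carry an exact
per-member substitution count solved from
(1−q)² + q²/3 = within-family identity, keeping realized pairwise
identities within ±2 points of the request (asserted). Nontargets are
ancestor copies mutated to the requested divergence. Genes default to
300 nt (functional-gene amplicon scale) with 4 members per family across
6 families — small enough to screen exhaustively at desk scale, large
enough to exercise every downstream stage.

## Signal analysis conventions

* Background per subarray: mean and sample sd (n−1) of the negative
  controls; ≥ 2 negatives required. SNR = (raw − mean)/sd; positive iff
  SNR > 2 (strict). Zero background sd makes SNR undefined: the spot is
  flagged and called by raw > mean, with a log message.
* Net intensity = raw − background mean, floored at 0 for calling and at
  1 intensity unit for ratios and log transforms (logged when floored).
* PM/MM: ratio of floored nets; a pair is ratio-positive when the PM
  spot is itself a positive call **and** the ratio exceeds 1.3. The
  PM-call condition matters: with both probes at background the floored
  ratio exceeds 1.3 about half the time by chance, so an unconditional
  ratio rule would call absent targets at ~50 %; conditioning on the PM
  call keeps the false-positive rate at the SNR rule's few percent while
  changing nothing for genuinely hybridized spots.
* CORS normalization scales each array by global-mean-CORS /
  array-mean-CORS: idempotent, equalizes CORS means across arrays, and
  preserves within-array ratios exactly.
* Detection across replicates: positive in a majority of replicates
  (2 of 3) — the per-spot SNR rule is published, the replicate rule is a
  declared convention, configurable.
* Quantitation: per-probe least squares of log10(mean net) on
  log10(mass) over detected points only; probes with < 3 detected points
  are excluded and counted; points at the saturation ceiling are flagged
  because they bias slopes downward. A total-signal fit sums net
  intensity over all detected spots.
* Diversity: richness = detected genes; H′ = −Σ pᵢ ln pᵢ over relative
  normalized intensities of detected genes (natural log; intensity as
  abundance proxy); evenness = H′/ln(richness), undefined at richness
  ≤ 1. Abundances are reported per probe, never per covered CDS — how a
  group probe's intensity distributes over many covered sequences is
  not identifiable from array data.
* Group comparisons: relative difference (m₁ − m₂)/max(m₁, m₂) and a
  two-sided Mann–Whitney U test (exact for small tie-free samples),
  significant at two-tailed p < 0.1 (one-tailed 0.05), no
  multiple-testing correction by default (Benjamini–Hochberg available).
  Note an exact two-sided U test cannot go below p = 0.1 with 3-vs-3
  samples; at least 4 samples per group are needed for any gene to reach
  significance under the exact null. Tests require ≥ 3 samples per
  group; smaller groups are skipped with a warning.

## Randomness and provenance

Each run derives a root RNG from a single seed; stochastic stages draw
from substreams keyed by a CRC of the stage name, so adding stages never
perturbs earlier stages' draws. Every CLI command writes a provenance
YAML (tool version, command, seed, fully resolved config) next to its
outputs; unknown configuration keys are rejected rather than ignored.

## Problem sizes

The test and acceptance workloads use desk-scale universes chosen to
exercise every code path while keeping exact (non-heuristic) screening
practical: 2–6 gene families of 2–4 members (200–300 nt genes), a
handful of nontargets per family, candidate steps of 5–20 nt, dilution
series of 5–8 points with 3 replicates, and 1,000-pair oracle
comparisons for the alignment kernels. Scanning real probe sets against
nucleotide databases at NCBI scale would require a heuristic pre-filter;
`screen_*` accepts a pre-filtered subject list for that purpose, and the
pre-filter itself is out of scope.

## Known limitations

* Heteroduplex ΔG ignores mismatch-specific stabilization; the screen is
  intentionally coarse and calibrated thresholds must be used with a
  comparably coarse model.
* The cross-hybridization yield curve is qualitative; absolute simulated
  detection limits are parameter choices, not predictions.
* Identity is ungapped; a gapped mode (match +1, mismatch −1, gap −2,
  identity = matches/L) exists behind the screen API but is off by
  default and not used by the published criteria.
* No physical spot placement, image gridding or wet-lab protocol
  modeling.
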