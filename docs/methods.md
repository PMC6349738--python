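# Methods

## Data model

A recording is an ordered list of waveform events tiling `[0, duration_s]`
with half-open intervals `[start, end)`: exact tiling, no double counting.
The canonical annotation dialect is two delimited columns (waveform label,
onset seconds), rows sorted by onset, first onset 0, an optional terminal
`end` row carrying the recording duration. Onsets are real-valued seconds;
the reader does not snap them to the 100 Hz display grid (annotation
precision exceeds the display rate — discretization is the verification
oracle's job, not the parser's). Adjacent events sharing a code are merged
on read: annotators habitually split segments, and event counts are only
meaningful under the merged convention. Default recording length is
43 200 s (12 h) and the nominal sampling rate 100 Hz is carried as metadata.

Grammar rules checked on every recording (violations are data, not
exceptions): every E2 is immediately preceded by E1 (or a continuing E2);
pd occurs inside probes, never adjacent to np; a probe opening directly
with phloem phase from np is flagged as a warning; the recording must be
non-empty. The first two are hard errors because downstream parameters
(time to first E2 within its probe, pd-in-pathway merging) presuppose them.

## Feeding model

**Probes.** A probe is a maximal interval of non-np events flanked by np or
a recording boundary. A probe truncated by the 12-h cutoff is still a probe
and is flagged `censored`; fixed-duration designs make truncation
unavoidable, and no censoring adjustment is applied to durations (truncated
events enter totals, means and sustained counts at their observed length).

**Early-G reclassification** (`early_g_threshold_s`, default 600 s). A G
event whose onset is strictly less than 10 min after the start of its probe
is relabeled F: the stylet cannot plausibly reach xylem within 10 min of
penetration, so such patterns are penetration difficulty, not xylem
ingestion. Strict `<` at the boundary. The rule is applied before any
parameter computation (the engine refuses unreclassified recordings), is
idempotent, and conserves total time.

**pd-in-pathway** (`merge_c_across_pd`, default on). Potential drops are
intracellular punctures *during* pathway; a maximal run `C (pd C)*`
collapses to one C event carrying the summed C duration while the pds stay
events of their own. This is the convention under which pathway counts,
means and totals are mutually consistent (count(pd) × mean(pd) equals total
pd time, and count(C) × mean(C) equals total C time, simultaneously). The
raw-segment convention is available behind the flag.

**Sustained events** (`sustained_threshold_s`, default 600 s, strict `>`):
the committed-ingestion criterion for both E2 and G. The sustained-G count
reuses the same 10-min threshold as sustained E2; this is an explicit
assumption, exposed through the same config field.

**Short C events** (`short_c_threshold_s`, default 180 s): merged C events
strictly shorter than 3 min, the conventional short-probe cutoff in the EPG
literature. Whether "short" counts C events or probes is ambiguous in
common usage; the default counts C events, with `short_unit: probe` as the
alternative.

**Missing values.** "1st E" means the first E1 onset — phloem-phase entry;
E1 precedes E2 by grammar, so this is the earlier and better-defined event.
An insect lacking a waveform contributes a missing value (flagged censored)
to the dependent parameters rather than the recording length, so
per-parameter group sizes vary and the share of insects showing E2 at all
is reported separately; the alternative convention is available as
`censor_policy: max_time` (applied to the three global latencies). The E1
share of the phloem phase is `100·E1/(E1+E2)` over E1+E2 time only — a
two-component share, with G and pd excluded — and is missing iff the insect
has no phloem phase.

Storage units are always seconds; display conversion (minutes generally,
pd and E1 event means in seconds, the first-probe-to-phloem latency also in
hours) happens only at table-export time, and all statistics run on
unrounded storage values.

## Simulator

First-order semi-Markov process over six macro states (np, C, G, E1, E2, F):
an embedded Markov chain with lognormal sojourn times per state. Lognormal
because behavioral durations are strictly positive and right-skewed — which
is also why the analysis pipeline needs power transformations. pd is not a
chain state but a marked point process inside C sojourns (Poisson number of
insertions per minute of pathway, lognormal durations, at least one 10-ms
sample of C kept on each side), preserving the pd-in-pathway convention.
Grammar holds by construction: E2 is reachable only from E1, probes open
from np into pathway, and profile validation rejects any transition matrix
with probability mass on forbidden pairs.

Event boundaries are quantized to the 10-ms acquisition grid (every sojourn
at least one sample), so a sample-level expansion of a simulated recording
reproduces its durations exactly — this is what makes the brute-force
verification oracle exact rather than approximate. Randomness comes from
numpy's PCG64 generator with integer seeding; cohorts spawn per-insect
streams from a single `SeedSequence`, so outputs are bit-reproducible across
runs and platforms.

The four built-in profiles emulate the canonical group contrasts of a
whitefly host-suitability study: `host_adapted` (mean sojourn targets
C ≈ 10.3 min, pd ≈ 6 s, G ≈ 37 min, E1 ≈ 66 s, E2 ≈ 260 min, F ≈ 19 min,
np ≈ 5 min), `phloem_rejection` (short, rare E2 and a high salivation share
— many insects never sustain ingestion), `delayed_acceptance` (first np
sojourn drawn with mean ≈ 99 min), and `thick_wire` (many short probes,
elevated F). Transition probabilities were set once so that expected event
counts per 12 h have the right magnitudes. Profile numbers are emulation
targets, not claims: the simulator reproduces magnitudes and contrasts, not
letter groupings, of any real dataset.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: inter-event dependence beyond first order (e.g.
refractory effects after long ingestion), within-insect heterogeneity over
the 12 h, diurnal drift, annotation error, or correlated group variances.
It produces clean, grammar-valid annotations; the pipeline's robustness to
annotator quirks is exercised separately (merging, dialect spellings,
malformed-input contracts).

A recording truncates its final sojourn at 43 200 s, so empirical sojourn
means computed from event lists are censoring-biased for long-duration
states. The simulator therefore exposes the raw pre-truncation draws
(`SimulationTrace`); distribution-recovery checks run on the draws, where
the lognormal mean is recovered without bias. Calibration checks use
n = 200 recordings (≈ 300–7 600 draws per state), chosen to put the
Monte-Carlo standard error of each state's mean well inside the 10 %
recovery band.

## Statistics

One-way fixed-effects comparison per parameter. The design has a single
between-insect factor and one observation per insect, so a mixed-model
formulation reduces to fixed-effects ANOVA; no random-effect structure is
modeled.

**Transformation.** Box-Cox exponent chosen from the grid −3 … 3 in steps
of 0.25 (the conventional search span; finer steps add nothing at these
group sizes) by maximizing the profile log-likelihood, λ = 0 meaning log.
Proportion-typed parameters — the E1 share of the phloem phase, plus any
parameter declared a percentage in configuration — are arcsine-square-root
transformed first. Zeros are handled by an additive shift of half the
smallest positive value, recorded in the output. Visual Q-Q inspection is
replaced by this numeric criterion; a Shapiro-Wilk statistic on the
transformed values is reported for audit. Constant samples and samples with
fewer than 4 values are rejected as degenerate.

**Tukey-Kramer.** Pooled error variance on N − k degrees of freedom;
pairwise statistic `|m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j))` referred
to the studentized-range distribution (scipy). With k = 2 and balanced
groups this reduces exactly to the pooled t-test, which the test suite
checks in closed form; unequal-n results are cross-checked against an
independent implementation. If MSE is exactly zero, equal means give p = 1
and unequal means p = 0.

**Letters.** Insert-and-absorb: start with one column holding all groups;
for each significantly different pair, split every column containing both
(duplicating the column and deleting one member from each copy); absorb
duplicates and proper subsets; order columns by first appearance and assign
letters a, b, c…. The defining display property — two groups share a letter
iff their adjusted p ≥ α — holds by construction and is re-verified by
brute force on every analysis run with ≤ 8 groups. Discontinuous strings
("ac") are legitimate and expected when standard errors of differences
vary. Letters depend only on the significance pattern, hence are invariant
to affine rescaling of the transformed values.

Group means are reported on the original scale next to the letters;
transformed-scale means and t-based confidence intervals go to a
supplementary table. A parameter that cannot be analyzed (a whole group
missing, or degenerate values) is reported with a skip reason, never as an
exception.

**QC accounting.** Recording success = full-length recordings / wired
insects; retention = recordings surviving quality screening / full-length
recordings. Which recordings are "bad" (noise, leaf detachment, damaged
insect) is a human judgment taken from the metadata status column — the
pipeline never infers it. Percentages are reported rounded to integers with
exact values retained.

## Numerical conventions

- All interval arithmetic in float64 seconds; the engine is verified
  against a 100 Hz sample-expansion oracle to 1e-9 s on durations and
  exactly on counts (200 recordings across all profiles in the test suite).
- Boundary conventions are strict throughout: early-G `< 600 s`, sustained
  `> 600 s`, short-C `< 180 s`.
- Ties in the Box-Cox grid resolve to the first maximizer (most negative λ);
  in practice the profile likelihood is unimodal on this grid.
- Degenerate inputs: all-np recordings yield zero counts and all-missing
  time-to-event parameters; empty cohorts and constant samples raise.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
oracle verification on 200 recordings (50 per profile), grammar soundness
on 1 000, sojourn recovery on 200, end-to-end group discrimination at
n = 15 per group, null familywise-error calibration over 400 replicate
4-group runs. These sizes were chosen to keep Monte-Carlo error small
relative to every tolerance while the whole suite completes in well under
a minute of CPU beyond the oracle pass.

## Known limitations

- The engine implements the reported parameter battery plus its obvious
  completions, not the full ~100-parameter workbook tradition.
- No survival-analysis treatment of censored time-to-event parameters and
  no nonparametric fallback when no transformation normalizes a parameter.
- E2 sub-variants and oviposition-related waveforms are not distinguished.
- The binary layout of proprietary annotation exports is out of scope; the
  canonical dialect here is plain text, and converters are future work.
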