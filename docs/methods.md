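# Methods

## Data model

Observations are instantaneous scan samples of a dam's behavior: one code
per 3-min slot over a 72-min period, inclusive of the start, so each session
holds exactly 72/3 + 1 = 25 codes. Three sessions are observed per
postpartum day (PPD 2–9): `AM` (9:00) and `PM` (14:00) in the light phase
and `DARK` (18:00) at the start of the dark phase, giving 75 scans per 24-h
cycle. The two light periods are *averaged*, not concatenated, wherever a
light-phase quantity is formed — their behavioral profiles are treated as
exchangeable — and the dark phase is always the single 18:00 session.

Seven codes are scored (`HG, LW, SUP, L, HG/L, DN, OFF`). `HG/L` (high
crouch while licking) is a first-class code rather than a flag pair, because
licking overwhelmingly co-occurs with high crouch and the combination
behaves as its own network node. Standalone licking `L` is scored and
analyzable as a frequency response but is not a network node. Non-pup-
directed events (nest building, pup retrieval, self-grooming, pups off
nest) ride along as per-slot auxiliary annotations; they can be tabulated
with the same response machinery but never enter transition counting. When
a non-nursing event co-occurs with a nursing posture other than HG, it is
recorded as an annotation; no further composite codes are invented.

## Transition counting and networks

A transition is an adjacent pair of scan samples with different codes,
counted strictly within one period (the gaps between periods contain hours
of unobserved behavior). Two scopes exist:

* the **fragmentation statistic** counts changes on the raw 7-code
  sequence (used for the per-phase "behavioral transitions" response);
* the **network scope** first removes `L` slots and counts changes between
  the six nodes; it equals the off-diagonal sum of the transition matrix.

Since `L`-removal is not uniquely defined, both defensible policies are
implemented and logged in every run's provenance: `bridge` (default)
deletes `L` slots and lets their neighbors become adjacent, preserving
continuity; `drop` discards any pair touching an `L` slot. The default is
`bridge` because deleting information about an ongoing bout seemed the
greater distortion; nothing downstream depends on the choice structurally,
and the CLI exposes both.

Per dam and day, the light-phase matrix/occurrence vector is the
element-wise mean of AM and PM; group networks are element-wise means over
dams (so weights may be fractional). Self-links are structurally excluded:
remaining in a behavior is not an event.

## Centrality

In-strength and out-strength are column and row sums of the weight matrix.
Betweenness uses fractional shortest-path counting: for ordered pair
(s, t), node v receives σ_st(v)/σ_st. Two edge-length conventions are
provided:

* `binary` (default): an edge exists iff its weight is positive, unit
  length. This is the classical count-of-shortest-paths definition and
  involves no weight-to-distance convention.
* `weighted`: length 1/w, so frequently used transitions are "short".

The chosen mode is recorded in run provenance and in the centrality tables'
metadata column ordering. Distances and path counts come from a per-source
Dijkstra sweep with path-count accumulation; equality of path lengths is
tested with a 1e-12 relative tolerance (exact for binary lengths). Raw
betweenness is reported unnormalized — z-scoring removes scale anyway.

Z-scores are computed within one network across its six nodes, with the
*population* SD (the six nodes are the whole population of the network, not
a sample). A constant vector maps to all zeros rather than NaN.

## Mixed repeated-measures ANOVA

The design is a balanced split-plot: housing (between, g = 2 groups),
postpartum day (within, d = 8 levels), n dams per group, each dam measured
every day. The classical univariate decomposition is used:

    SS_total = SS_housing + SS_subjects(groups) + SS_day
               + SS_day×housing + SS_day×subjects(groups)

with housing tested against subjects-within-groups (df g−1, g(n−1)) and day
and interaction against day×subjects-within-groups (df d−1 and
(g−1)(d−1), over (d−1)g(n−1)). For 2 × 9 × 8 this yields F(1, 16) and
F(7, 112). No sphericity correction is applied by default — the reported
df of the target design are the uncorrected ones — but a Greenhouse–Geisser
option recomputes the within-factor p-values from ε-scaled df. Unbalanced
inputs are rejected, not approximated: the intended design is balanced, and
silently switching to an approximate method would change the estimand.

Degenerate inputs (zero error variance): if the effect variance is also
zero the test reports F = 0, p = 1 (and logs a warning); a nonzero effect
over zero error reports F = ∞, p = 0.

Per-day group contrasts use t = Δmean / √(MS_subj(groups)·(1/n₁+1/n₂))
with df = g(n−1) — the pooled between-subject error — and a Šídák
adjustment p_adj = 1 − (1 − p)^m over the m = 8 days compared. Using the
between-subject mean square (rather than a per-day variance or a
Satterthwaite blend) is an interpretive choice: it matches the family
"group difference within each day" tested after the mixed model, and is
exact under compound symmetry.

SEM is the sample SD (ddof = 1) divided by √n.

## Synthetic generator

Each (group, phase-class) condition is a discrete-time Markov chain over
the 7 codes, factored as T_d = (1−f_d)·I + f_d·K with a zero-diagonal
row-stochastic kernel K and day-dependent switch probability
f_d = clip(f + drift·(ppd−2), 0, 1). The factorization makes fragmentation
a one-parameter manipulation — the expected per-session transition count is
exactly 24·f_d — while K controls *where* the dam goes when she switches.
Kernels are parameterized by a single repertoire vector: row i is the
vector renormalized without entry i, so destinations are drawn in
proportion to each behavior's overall prominence in that condition.

Default presets (all values are tuning choices; no dwell-time data exist
to calibrate against):

| condition  | repertoire emphasis              | f    | drift/day |
|------------|----------------------------------|------|-----------|
| CTRL light | HG-dominant (0.40), DN/LW next   | 0.35 | −0.015    |
| LBN light  | HG boosted (0.50), SUP cut (0.03)| 0.35 | −0.015    |
| CTRL dark  | OFF-dominant (0.45)              | 0.35 | −0.015    |
| LBN dark   | HG boosted (0.30), OFF cut (0.24)| 0.50 | −0.015    |

These reproduce the intended qualitative sign pattern: high crouch elevated
in LBN in both phases, supine suppressed in the LBN light phase, transition
counts declining with day everywhere, and a housing effect on transitions
only in the dark phase. Standalone `L` is kept rare (1–2%) in every
condition.

Determinism: a single global seed; each dam draws from a private stream
spawned with a stable (group, dam) key, so enlarging the experiment never
reshuffles existing dams. AM and PM draw independent sessions from the same
LIGHT profile.

What the generator does **not** emulate: dwell-time distributions beyond
geometric (no semi-Markov structure), pup-state feedback, litter-size or
cohort effects, circadian drift within a period, observer error, and any
dependence between the three daily sessions beyond sharing a profile.
Consequently, passing tests demonstrate that the pipeline recovers the
structure this model puts in — directions of effects, calibration of the
test under the null — not that real maternal behavior is Markovian.

## Numerical and I/O choices

* Shortest-path tie tolerance 1e-12 (relative); weight-0 edges are absent,
  no epsilon flooring.
* TSV floats are written with `%.10g`; rows are canonically ordered, so
  identical configs and seeds give byte-identical outputs.
* All artifacts are written atomically (temp file + rename); a failing run
  leaves no partial file, and the dataset is validated before any output
  directory is created.
* Run provenance (`run_config.json`) serializes the full simulation
  profile set, seed, policies and library versions.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which each check is statistically sharp:
the betweenness oracle covers all 4 096 four-node digraphs plus 500 random
weighted six-node graphs in both modes; kernel recovery uses 40 000
simulated sessions (≈3.4×10⁵ transitions, entrywise tolerance ±0.02); the
mean-transition check uses 10 ⁴ sessions (±0.05 of 24·f_d); type-I-error
calibration runs 2 000 null experiments at the full 9-dams-per-group
design (acceptance band 0.03–0.07 at α = 0.05); the qualitative-direction
check runs 200 full simulated experiments.

## Known limitations

* Betweenness on dense group-averaged networks is frequently zero in
  binary mode (most node pairs are directly connected); the weighted mode
  is more informative there and both are exported.
* The Šídák contrasts assume homogeneous between-subject variance across
  groups and days (compound symmetry); with strong heteroscedasticity a
  per-day Welch contrast would differ.
* The ANOVA is the classical univariate mixed model, not a REML linear
  mixed-effects fit; with balanced complete data they coincide for these
  F tests, but missing data are rejected rather than modeled.
* Network averaging across dams describes the group-mean transition
  structure; it does not capture between-dam strategy heterogeneity.
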