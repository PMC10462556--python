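# Methods

## The process model

A procedure is a sequence of *modules* — surgical steps at surgeme
granularity, coded `PxxMyy` (phase, module) — plus zero-duration *questions*
(decision points). The timed phases are imaging (05), planning (06),
operative field access (07), destructive isolation (08a), treatment (10),
intra-operative complications (11) and wrap-up (13). Three tumor-location
categories have distinct workflows:

* **S56** — segments 5 & 6, no gallbladder removal. Mid-resection loop: the
  surgeon may repeatedly interrupt resection to isolate, possibly occlude,
  and divide a supply duct (each 60% likely to occur at all); the
  probability of dividing *yet another* duct decays with the number already
  divided.
* **S78** — posterosuperior segments 7 & 8. No supply-duct
  isolation/occlusion/division occurs; imaging is much longer (poor
  laparoscopic access and visibility).
* **S5GB** — segment 5 with cholecystectomy. A mandatory ordered chain:
  mobilize gallbladder → isolate → permanently occlude (clips) → divide the
  cystic ducts, each present in every surgery.

Graphs are data, not code (`llrsim/data/workflow_*.json`, schema
`llrsim-workflow/1`): node labels with occurrence probabilities (the chance
the module occurs once or more), free-order groups (the wrap-up block),
mandatory precedence pairs (compared on first occurrences), untimed modules
(desufflation and incision closing happen after the camera leaves the
abdomen), and insertable-anytime nodes (imaging, planning, intra-operative
leakage clean-up). Imaging/planning are modelled as insertable nodes rather
than edges from every node; this keeps the graph bounded with the same
expressive effect. Two rows of the published workflow table carry no
percentage; gallbladder mobilization is assigned 1.0 (it belongs to the
mandatory chain) and liver mobilization keeps its printed 0.4.

## Step-log registration rules

One CSV row per executed module with start/end seconds of endoscopic video
time. Consecutive records in the same module are one occurrence
(`collapse_repeats`; merging never changes a module's time footprint).
Ultrasound imaging (P05M02) may run in parallel with planning (P06M01) or
region marking (P10M01); any other overlap is an error. Overlapped planning
time counts toward imaging — the planning statistic is "planning without
imaging" — while parallel marking keeps its full duration and both count an
occurrence. Planning may be instantaneous (zero duration); insufflation
(P07M02) carries zero duration because it is not recognizable on video.
Leakage clean-up is two distinct modules by design: during treatment it is
a complication (P11M02, can happen anytime); during wrap-up it is part of a
normal procedure (P13M04); they are never merged. Idle intervals (lens
cleaning, no visible activity) are explicit `IDLE` records. The fixed
intra-operative preparation hour (3600 s) is a constant excluded from
endoscopic totals by default.

## Bundled summary parameters

`llrsim/data/reference_stats.json` (schema `llrsim-stats/1`) carries the
published per-category tables: per-module duration mean/SD in seconds
(over occurrences in surgeries where the module occurred) and occurrence
mean/SD (over all surgeries, zeros included — an occurrence mean may be
below 1), the idle mean/SD, the minimum observed resection times
(476/540/922 s for S56/S78/S5GB) and the preparation constant. One
packaging row of the source table is typographically ambiguous; the
resolution used (S78: 63 (20) s, occurrence 1 (0); S5GB: 138 (3) s,
occurrence 1.3 (0.6)) is editable data, not a code constant.

## The simulation engine

A run draws, for every timed module, an occurrence count and that many
per-occurrence durations; the total is the sum over modules plus two fixed
per-surgery additions. Module order cannot change the total, so batches
sample module-wise (vectorized); `simulate_run` wraps the same core for a
single run.

**Durations.** Gaussian mode fits N(mean, SD) and ignores the negative
tail: sampling is from the zero-truncated normal (scipy `truncnorm`), a
skewed non-symmetrical distribution with no point mass at zero. Uniform
mode draws between per-module bounds — observed min/max when raw logs are
supplied, otherwise moment-matched bounds `[max(0, μ−√3σ), μ+√3σ]` (mean μ,
SD σ whenever μ ≥ √3σ). SD 0 degenerates to the constant mean.

**Occurrence counts** are `round(max(0, N(occ_mean, occ_sd)))` with
round-half-away-from-zero (platform-independent ties). Zero counts are
possible even for modules present in every recorded surgery; that is the
point of the exclusion criteria — without a lower bound, unreasonably
small resection times (down to zero) would occur. The observed workflow
percentages emerge from these count distributions (e.g.
P(N(0.2, 0.4) ≥ 0.5) ≈ 0.23 for the 20%-probable fat/adhesion dissection).
Dynamic questions ("divide yet another duct?") are evaluated as the
survival function P(count > n) of the count distribution: non-increasing
in the execution counter and zero beyond the support.

**Fixed additions.** Intra-operative leakage clean-up and idle are added as
per-surgery means rather than simulated events: leakage = duration mean ×
occurrence mean of P11M02 (a `per_occurrence` policy uses one mean
occurrence instead), idle = the idle mean. Neither is affected by the
navigation platform. Questions take zero time. The preparation hour is not
added by default.

**Exclusion** is post-hoc and boundary-inclusive: a run is excluded when
fewer than 3 trocars were placed, or when the resection total is strictly
below half the category's minimum observed resection time (238/270/461 s).
Each excluded run carries one primary reason (trocars checked first).
Batch summaries (mean, SD, KDE peak) are over included runs only.

**Reproducibility.** One seeded root generator; batches consume numbered
`SeedSequence` substreams recorded in the pipeline run log, so any cell can
be replayed in isolation. Matched seeds across scenarios consume identical
random streams, which makes scenario comparisons pointwise monotone when
one scenario dominates the other.

## Navigation-platform scenarios

Scenario 1 is the baseline (identity). Scenario 2 (conservative): resection
×0.90, supply-duct isolation ×0.75, physical marking removed, and a
per-model-update computational cost of 60 s segmentation + 120 s
image-to-3D-model registration + 120 s new images = 300 s. Scenario 3
(optimistic): resection ×0.80, isolation ×0.50, 30 + 60 + 120 = 210 s.
Image-to-patient registration is assumed pre-operative and free in-run; no
re-registration events are simulated (no significant patient repositioning).
Multipliers scale both μ and σ (and both uniform bounds): a faster action
is taken to be proportionally less variable.

The imaging policy is the one genuinely open design choice. By default
scenarios 2–3 **replace** each ultrasound imaging event's duration with the
technology-step sum — the updated 3D model takes over the role of
intra-operative ultrasound. This is the only reading under which the
platform's benefit concentrates in S78, whose imaging is by far the
longest; pure addition of the technology time on top of unchanged
ultrasound *lengthens* surgeries. The `add` policy is available as a
config switch, and the acceptance tests sweep both imaging policies and
both leakage policies.

Impact metrics: percent decrease of the mean total duration,
`100·(1 − mean_Scx/mean_Sc1)` (negative values allowed), and the analogous
decrease of the most probable duration — the mode of a Gaussian KDE with
Silverman bandwidth evaluated on a 1-second grid (≥ 100 samples required).

## The synthetic cohort generator

The generator emulates the *recorded* cohorts: every downstream stage is
testable without the deposited videos. Defaults equal the bundled tables.
Per surgery, each module is present with its workflow probability; present
modules draw a conditional count `round(max(N(μ*, occ_sd), 1))` — in an
observed log a present module occurs at least once — and per-occurrence
durations from a zero-truncated normal. Because truncation and rounding
shift raw moments, μ* is obtained by numerically inverting the exact
truncated/rounded expectations (Brent's method) for both durations and
counts, with the conditional count mean targeted at
`occ_mean / presence` so the unconditional mean matches the table. The
statistics recovered by `module_stats` therefore converge to the published
values (tested at n = 2000 within 3 standard errors for duration means,
occurrence means and presence probabilities).

Occurrences are laid out along the workflow: trocars/insufflation,
pre-resection dissection and mobilization (for S5GB the mandatory chain,
round-robin so first occurrences keep the chain order), marking, resection
with the S56 duct loop interleaved between resection occurrences, then the
wrap-up free-order group in a shuffled round-robin. Imaging, planning and
complication clean-up float anywhere; they are preferentially placed where
two same-module records would otherwise touch (and be collapsed into one
occurrence by the registration rules), with thin slices of the idle budget
as a fallback — so the idle total may be split across more than one record.
All generated logs pass verification; identical seeds give byte-identical
cohorts.

What the generator does **not** emulate: surgeon identity, patient
covariates (BMI, adhesions, prior surgery), lesion-size effects,
inter-module correlation (a slow surgery is slow everywhere), or real
parallel imaging/planning records. Passing recovery tests shows the
analysis chain is self-consistent at the category level, not that it
captures individual-surgery structure beyond the published summaries.

## Problem sizes and numerical choices

Simulation cells use 45,000 runs (two such batches of one configuration
differ by well under 0.5% in mean and SD; a batch takes well under a second
on one CPU, the full 3 × 3 × 2 category/scenario/mode grid a few seconds).
Parameter recovery uses cohorts of 2000 synthetic surgeries with 3-SE
tolerances computed from the cohort itself. Times are seconds with one
decimal on disk (step-log round-trips are bit-exact); generated
non-planning records are floored at 0.1 s so truncated draws cannot
serialize to zero-length steps. Sample SDs use ddof = 1. Phase-breakdown
fractions are normalized over included phases and sum to 1 within 1e-12;
the fat/adhesion dissection module is excluded by default (its duration is
dominated by patient factors), and idle/complications are excluded from
the phase denominator by default — both are flags, since the published
normalization is not fully specified.

The greedy most-probable-path extraction consumes transition counts as it
walks (start at the most frequent first module; at each step take the most
frequent remaining outgoing transition, ties by module-code order), which
bounds the path and lets supported loops appear; it reproduces a single
surgery's collapsed sequence when transitions are unambiguous, and the
majority sequence in cohorts dominated by one ordering.

## Known limitations

* Simulated totals are mildly biased upward relative to a naive
  mean × occurrence product: the engine deliberately keeps the published
  model's truncation inflation (a Gaussian fitted to a long-tailed
  duration, truncated at zero, has a mean above the printed one —
  strongest for S78 imaging, 1259 (1491) s). The generator inverts this
  bias because it targets observed statistics; the simulator does not,
  because the truncated fit *is* the published model.
* Scenario impacts for imaging-heavy categories are sensitive to the
  imaging policy (replace vs add) and, secondarily, to the leakage
  addition policy; both are exposed in configuration and swept in tests.
* No operating-room resource model: no staff, no scheduling, no event
  calendar with true concurrency — parallelism is reduced to the
  attribution rules.
* Only duration is modelled; no clinical outcomes, costs, or learning
  effects.
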