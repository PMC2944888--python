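# Methods

## Model and assumptions

The simulator implements threaded cognition over a small set of serial
cognitive resources: procedural, declarative, problem state, visual,
aural, manual. Any number of task threads may be active, but each
resource serves one request at a time; a thread blocks until its
requested resource is free. Conflicts are resolved by a
least-recently-served policy per resource, with ties broken by a fixed
thread order (subtraction < text entry < listening). The policy is a
design choice — the theory requires only serial resources — and in this
task it is almost inert: the forced digit/letter alternation serializes
the two manual tasks, so only the listening thread genuinely competes
(for procedural and declarative steps).

Time is integer microseconds internally, so simulated traces are exactly
reproducible; the public interface is milliseconds. Threads are
generators yielding resource requests; the engine logs every granted
step as a busy interval, and the per-resource interval lists form the
demand trace.

### Step timings

| action | default | note |
| --- | --- | --- |
| procedural step | 50 ms | |
| visual encode | 85 ms | |
| declarative retrieval | 60 ms | |
| mouse move + click | 250 ms | |
| problem-state update | 200 ms | the architecture's established estimate |
| aural perception | word duration | overlaps central processing of the previous word |

Only the 200 ms update cost and the ~320 ms aggregate per-word listening
cost are externally fixed; the remaining values are conventional module
durations chosen so that the listening thread's four procedural steps
and two retrievals add to exactly 4·50 + 2·60 = 320 ms. All are exposed
in `StepTimings` / the pipeline config.

### Problem-state semantics

The slot holds one chunk. A *swap* is any replacement of a non-empty
slot's occupant by a different thread's chunk: the occupant is suspended
to declarative memory and the needed state is retrieved back (60 ms,
wrong with probability `p_wrong_state`, default 0.05) and installed
(200 ms). The hard subtraction thread installs a "no borrowing in
progress" state at its first column and consults the slot at every
resume; the hard text-entry thread's first per-letter update creates its
(word, position) chunk. These conventions make a hard–hard trial swap
exactly 19 times — every task resume from the second turn on — and
single-hard or easy–easy trials swap zero times. A borrow writes the
flag at the borrow column (after a re-look at the digits, an add-ten
step and a second fact retrieval) and an update clears it at the first
later column without a new borrow; updates are emitted only when the
flag changes. A stale restored state makes the owning thread's next
response incorrect and nothing else — the simplest mapping of retrieval
errors onto behaviour, which keeps trace timing independent of
`p_wrong_state`.

### Listening and word misses

A word is perceived aurally for its full duration; its central
processing (retrieval, 2 procedural steps, retrieval, 2 procedural
steps) becomes eligible when perception ends and is **dropped** if it
cannot start before the next word has also been perceived (a one-word
buffer). The gate is the first retrieval, so a declarative module held
busy across a full inter-word window causes a miss. Missed words
contribute only a short initial aural perception (85 ms) to demand;
processed words contribute their full duration. Aural intervals are
derived from the word schedule plus miss flags after the run (the aural
module is never contested, and a missed word's shortened perception is
only knowable once the miss is decided). At the default timings,
declarative contention from the other tasks rarely blocks a full
inter-word window, so misses are rare in simulated trials; the mechanism
is exercised directly in the tests by forcing contention.

## Trials and sessions

A trial runs cue 5 s → fixation 1 s → tasks (onset at 6 s, on the 2 s
scan grid) → feedback 3 s, with inter-trial intervals drawn uniformly
from 13–17 s and rounded to the scan grid so scan indices stay integral.
Subtraction always starts; tasks strictly alternate via a turn token.
Text-entry RT is digit-entry to letter-entry, subtraction RT
letter-entry to digit-entry; first responses per task are flagged for
downstream exclusion. A session of 10 blocks × 9 randomized conditions
reproduces the 90-trial experiment; per-subject and per-trial seeds
derive deterministically from the master seed.

## BOLD prediction numerics

- Convolution grid dt = 50 ms (≤ the shortest step). Demand indicators
  use fractional bin coverage, so the binned busy time is area-exact.
- The gamma kernel is sampled at bin centres and truncated where it
  falls below 1e−8 of its peak (≈26 s at defaults); with both choices
  the discrete convolution conserves area to machine precision
  (output integral = busy time × discrete kernel integral).
- Curves are sampled at scan onsets (linear interpolation on the fine
  grid), placed on a nominal raw offset of 100 (grand-mean scaling), and
  baselined to the mean of a trial's first two scans; task onset at 6 s
  guarantees demand-free baseline scans for predictions.
- AUC is the plain sum of per-scan percent-change values (scan-count
  weighting, matching how windows are tabulated), not a trapezoid.
- The demand trace is cut at feedback onset — post-feedback events
  (question reading and answering) are outside the modelled trial — but
  the AUC integrates the full hemodynamic response of that demand,
  including the tail that peaks after feedback. Cutting the *response*
  at feedback instead would discard a condition-dependent share of each
  response's energy and break the conservation property that makes
  "equal total manual activity" a prediction; excluding post-feedback
  *demand* is the analysis's actual intent.
- Predicted condition means average a small number of simulated trials
  (default 3; stimuli differ by seed) — enough to stabilize borrow-column
  placement and story length, cheap enough for interactive use.

## Synthetic ROI data

Synthetic measurements emulate subject-averaged condition curves:

    raw = 100 + gain_s · mean_curve + AR1(σ_scan, ρ) + drift·scan
    (+ carryover·peak added to the two baseline scans),

then re-expressed as percent change against those baseline scans, exactly
as measured curves are. `gain_s` is lognormal (σ_subject = 0.2):
multiplicative between-subject BOLD scaling is the conventional
assumption. Scan noise is stationary AR(1) with ρ = 0.3 and marginal SD
σ_scan = 0.06% — interpreted as the noise of a ~10-trials-per-cell
average, and calibrated (before any acceptance checking of effects) so
the interaction test at n = 10 subjects has power in a realistic
0.5–0.9 band rather than at floor or ceiling. Carryover defaults to 0
and is switched on only to reproduce the non-return-to-baseline
phenomenon. Model curves carry arbitrary units (kernel magnitude m = 1),
so each ROI's condition means are rescaled to a 0.5% peak — a typical
slow event-related ROI amplitude — before noise is added.

What the generator deliberately omits: voxel-level structure, motion and
physiological noise, region-specific hemodynamics, nonlinear BOLD
saturation, and trial-by-trial behavioural/neural coupling. Passing
tests therefore show that the *analysis chain* is correct and calibrated
on data satisfying its assumptions, not that real scanner data would
satisfy them.

## Statistics

All tests are within-subject F tests on per-subject contrast scores over
the 2-level factors: F = n·mean²/var on (1, n−1) df, identical to the
squared paired t, with partial eta squared F/(F+df2); the three-way
design uses the same machinery over 8 cells. Zero contrast variance with
a nonzero mean reports F = +inf. RT outliers are removed in two passes —
absolute bounds 250–10,000 ms, then 3 SD per subject × condition cell on
the survivors (cells with fewer than two survivors are flagged and skip
the SD pass) — and accuracies are arcsin(√p)-transformed with no
continuity correction. No multiple-testing correction is applied
(α = .05 per test). AUC ANOVAs run separately per listening stratum,
mirroring how those results are tabulated.

## Known limitations

- The engine models one step per module action; finer pipelining,
  subsymbolic activation dynamics, production compilation and utility
  learning are out of scope.
- The listening thread is a resource-demand skeleton (no syntactic
  content); question comprehension is not modelled, which is why demand
  is cut at feedback onset.
- Mouse kinematics are a flat 250 ms click; easy-condition RTs are
  therefore faster than human data, compressing trial lengths while
  preserving every ordinal and interaction prediction.
- The packaged 10-letter word list is a hand-compiled synthetic stand-in
  for the original frequency-controlled stimulus list.
- Whether the kernel magnitude is global or per-module is unresolved in
  the prediction methodology; it is treated as global here, which is
  inert since only curve shape is interpreted.
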