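# Methods

This note documents the behavioral model the engine implements, the
parameters that matter, what the simulated subjects do and do not
emulate, and the design choices made where the design was genuinely
open.

## The engine

Everything is event-sourced. A task state machine runs against a
monotonic session clock (simulated by default, wall-clock for live use)
and appends timestamped events — trial starts, raw touches, registered
responses, tones, pellet commands, omissions, stage advances — to an
append-only log. The log is written as one comma-separated file per
subject (header + one line per event) and is the *single source of
truth*: trial outcomes and every session metric are reconstructed from
the file alone, so analyses are reproducible from data at rest.

The CSV schema (column order `subject_id, session_id, task, phase,
trial_index, event_type, timestamp_s, x, y, payload`) is this package's
own; the recording format it implements is simply "every response is a
new line in a comma-separated file, one file per subject". Timestamps
are seconds since session start at millisecond precision; coordinates
are fractions of screen width/height in [0, 1], origin top-left, which
keeps all layouts resolution-independent. The free-form `payload` column
holds `key=value;key=value` detail and is RFC-4180 quoted.

## Touch semantics

Pigs press and then swipe upward at a slight diagonal, so software that
acts on button *release* misses or misplaces their responses. Buttons
here respond on the initial press only; release events never register.
Each box may additionally expose an invisible touch region extending
*above* its visible rectangle (`hit_extension_above`, default 0 — off),
which absorbs presses that land slightly above the button. Overlapping
active touch regions are rejected when a layout is constructed, not at
hit time, so hit-testing is never ambiguous. Touch contact duration is
not modeled: a press and its release share a timestamp.

## Peripheral protocol

The rig is two nodes: the screen node sends single-character cue tokens
over a radio link; the peripheral node maps them to 28 V outputs. Cue
`"1"` cycles the pellet dispenser once; `"2"` turns the tone generator
on for 1 s. The link is modeled as an ordered, lossless channel; the
physical transport is a plug-in point (`pigscreen.hal.Transport`), and
the shipped mock transport can inject stray tokens to exercise
robustness, because stray radio pickup is a real failure mode. Unknown
tokens change no output and are logged as stray-signal notes. Two
hardening behaviors are explicit choices: a second tone cue while the
tone is on *extends* it (non-retriggerable extension), and an optional
watchdog forces any output off once no refreshing cue has arrived
within its timeout. Speaker cues are fixed: 2900 Hz (0.2 s) on every
registered press, 7500 Hz (0.5 s) at trial start; the durations are this
package's choice, the frequencies are the task's.

## Response shaping

Stage thresholds are 20 (stage 0), 15, 15 and 40 reinforced presses.
Stage 0 is autoshaping: on each illumination a pellet arrives 10 s
later regardless of behavior, but a press anywhere is reinforced
immediately under a concurrent FR-1. The overlap is resolved as: a
reinforced press **cancels** the pending Pavlovian delivery, so each
illumination delivers at most one pellet, and only contingent
deliveries count toward the stage threshold (noncontingent ones are
flagged `noncontingent=1` in the log). Stage 2 places a full-width band
of height 1/3 at one of three heights; stage 3 a square of side 40% of
screen width at one of five positions (0.05 corner offsets, center).
Position draws are uniform and independent — immediate repeats are
allowed. The optional stage 4 shrinks the square by a configurable
decrement (default 0.02) per reinforced trial down to a floor of 0.22,
resetting to 0.40 after an omission; pigs have been observed to track
squares down to about 22% of screen height, hence the floor default.

## Delay discounting

Large = 4 pellets, Small = 1. A session is one block per delay in
ascending order — default 0, 5, 10, 20 s, stepping every 12 trials —
each block being 6 forced trials (3 Large-only + 3 Small-only, order
shuffled) followed by 6 free choices. The delay applies to the Large
option only; Small always pays immediately. Forced-before-free and the
3+3 forced split are this package's choices (only "6 forced + 6 free"
is fixed by the task). Pellets cycle at 0.5 s intervals when several are
delivered. Button reversal flips which side carries Large and is an
involution; magnitude discrimination training is the same session with
the single delay 0, and advancement from it is experimenter-triggered
via config (the criterion in practice is a judgment call, not an
algorithm). The omission window is 60 s per trial (configurable); the
intertrial interval defaults to a fixed 15 s, deliberately under 20 s
so competing exploration does not take over.

## Color discrimination

A trial is: center (sample) box → fulfil its fixed ratio → two choice
boxes left/right → fulfil one choice box's ratio. In the simple and
correction phases the center and target are yellow and the comparison
is blue; in the conditional phase the center shows the sample (green or
blue, drawn uniformly per trial) and only the matching color is
reinforced. Sides are pseudorandom: balanced within blocks of six with
no more than three consecutive trials sharing a side. From the
correction phase on, an incorrect choice queues an immediate
re-presentation of the identical layout with the incorrect box rendered
inactive (visible, gray, dead); corrections do not consume planned
trials or side assignments and are excluded from the accuracy
denominator (the subject cannot get them wrong). FR-3 on sample and
choice buttons is a config switch (`fr_sample`, `fr_choice`).

## Simulated subjects

Agents choose by hyperbolic (Mazur-form) discounting `V = A / (1+kD)`,
greedy at temperature 0 (seeded tie-breaks) or softmax otherwise. One
interpretable parameter `k` (1/s) spans the full AUC range: a greedy
agent prefers Large exactly while `D < 3/k`. Side and color biases in
[−1, 1] enter as additive value offsets `±0.5 · bias · scale` where
`scale` is the largest option magnitude — scaling by the magnitude
*range* would vanish in discriminations where both options pay the same,
exactly where the preference indices need to move, so the maximum is
used instead. Touches aim at the box center with Gaussian scatter
(`touch_sd`) and an upward swipe offset; response latencies are
gamma-distributed with configurable mean and SD (SD 0 = deterministic);
omissions are a per-trial Bernoulli draw. All agent and task randomness
derives from the single session seed (recorded in the log header), so a
seed + config pair reproduces a session file byte-for-byte.

What the agents do **not** emulate: learning (acquisition curves,
within-session drift), frustration after withheld reinforcement,
rooting and other competing behaviors beyond a flat omission
probability, and sensory/discrimination error as such (a "biased" agent
errs through value noise, not misperception). Passing tests therefore
certify the *program contingencies* — schedules, geometry, logging,
metric arithmetic — not that live pigs would produce any particular
curve.

## Session metrics

All metrics are computed over trials reconstructed from the log, with
omitted trials excluded from every denominator. The discounting AUC
defaults to the task's own definition — the proportion of completed
free choices of Large, pooled across blocks, bounded in [0, 1] — which
is *not* the conventional discounting AUC; the delay-normalized
trapezoidal area over per-block proportions is provided as an explicit
`trapezoid` mode, and the two coincide at the endpoints. When all
blocks have equal completed free-choice counts the pooled proportion
equals the mean of per-block proportions. Preference indices are
(L−R)/(L+R) over completed, non-forced, non-correction choices (+1 =
all left) and (G−B)/(G+B) over green-or-blue choices (+1 = all green);
accuracy is 100 × correct / scored non-correction trials; initiation
latency is the mean time from the trial-start tone to the first
registered response.

## Numerical and scale choices

Timestamps quantize to 1 ms and coordinates to 1e-6 at record creation,
which is what makes the CSV round trip an exact identity. Default
problem sizes keep everything fast on one core: a full shaping run is
90 trials, a DDT session 48, discrimination examples 24–400 trials; the
whole test suite completes in seconds on the simulated clock.

## Limitations

No live touch backend ships — `hal.Transport` and the `run` CLI command
are the plug-in seam. The experimenter-delivered interventions that
accompany live testing (ketchup prompts, marshmallow DRO during ITIs)
are representable only as free-text `manual_note` events. No
cross-subject statistical inference is provided; the analytics are
descriptive per-session panels by design.
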