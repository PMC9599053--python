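# pigscreen

A hardware-independent operant task engine for **touchscreen behavioral
testing in pigs**: the task state machines, peripheral cue protocol,
per-subject CSV event logging, session analytics, and simulated subjects
needed to develop, test and analyze porcine cognitive tasks without
animals or hardware in the loop.

Pigs are an increasingly important model for neurological conditions
(traumatic brain injury, Alzheimer's, Huntington's), but automated
cognitive assays for them are scarce. A practical rig is a rack-mounted
touchscreen driven by a microcomputer, with a pellet dispenser and tone
generator across the room behind a radio cue link. `pigscreen`
re-implements that rig's entire program logic with the hardware behind a
pluggable abstraction, so every contingency is exact, testable and
reproducible.

## What it implements

- **Response shaping** — stage 0 is Pavlovian autoshaping (full-screen
  illumination, a pellet 10 s later, plus a concurrent FR-1 reinforcing
  any press); stages 1–3 shrink the target from the full screen to a
  band of 1/3 screen height at three random heights, then a square of
  40% screen width at five random positions. Advancement is automatic at
  20 / 15 / 15 / 40 reinforced presses; an optional stage 4 shrinks the
  square per consecutive correct trial.
- **Delay discounting (DDT)** — Large (4 pellets) vs Small (1 pellet);
  blocks of 12 trials (6 forced + 6 free) with the delay to the Large
  reinforcer climbing 0, 5, 10, 20 s across blocks; button reversal and
  alternative delay ladders as pure config transforms. The session AUC
  is the proportion of free choices of Large, in [0, 1].
- **Color discrimination** — yellow vs blue simple discrimination, a
  correction procedure (each error immediately re-presented with the
  wrong box visible but dead), and a conditional match-to-sample phase
  (green or blue sample dictates the reinforced color), with optional
  FR-3 on sample and choice buttons.
- **Peripheral protocol** — cue `"1"` cycles the pellet dispenser, `"2"`
  turns the tone on for 1 s; unknown (stray radio) tokens are logged and
  ignored; an optional watchdog forces stale outputs off. Speaker cues:
  2900 Hz on every registered press, 7500 Hz at trial start.
- **Touch semantics** — buttons respond on initial *press*, never on
  release (pigs press then swipe upward), and any box can carry an
  invisible hit region extending above its visible rectangle.
- **Simulated subjects** — agents choose by hyperbolic discounting
  `V = A / (1 + kD)` with optional softmax noise, side/color biases,
  touch scatter, swipe offset, latency and omission parameters. Same
  seed + same config → byte-identical session files.

Every response is one line in a comma-separated session file, one file
per subject; all analytics are recomputed from that file alone.

## Worked example

```python
from pigscreen import AgentPolicy, run_ddt_session, session_metrics

for k in (0.0, 0.1, 0.5, 2.0):
    log = run_ddt_session(AgentPolicy(kind="hyperbolic", k=k), seed=11)
    print(k, session_metrics(log).auc)
```

prints

```
0.0 1.0
0.1 1.0
0.5 0.5
2.0 0.25
```

A greedy hyperbolic chooser prefers Large exactly while `D < 3/k`: with
`k = 0.5` that keeps Large only in the 0 s and 5 s blocks (12 of 24 free
choices → AUC 0.50), and with `k = 2` only in the 0 s block (AUC 0.25).
Recovering the ordering of `k` from the AUC is the package's round-trip
sanity check on the whole stack: session plan → trial machine → touch
registration → event log → analytics.

The same flows are available from the shell:

```bash
pigscreen simulate --task ddt --agent hyperbolic --k 0.5 --seed 7 --out-dir sessions
pigscreen summarize sessions/pig1_s1.csv
pigscreen config   # print every default as YAML
```

See `examples/` for narrative scripts covering shaping, discounting,
discrimination and the peripheral protocol.

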