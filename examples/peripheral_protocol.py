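"""Exercise the two-node peripheral cue protocol, strays and watchdog.

The screen node sends single-character cues over the (mock) radio link:
"1" cycles the pellet dispenser, "2" turns the tone on for 1 s, anything
else is logged as a stray signal and ignored. A watchdog can force stale
outputs off if no refreshing cue arrives.
"""

import numpy as np

from pigscreen.core import SessionContext, SimulatedClock
from pigscreen.hal import make_peripherals, tone_active, watchdog_tick

ctx = SessionContext(subject_id="bench", session_id=1, task="ddt", clock=SimulatedClock())
link = make_peripherals(ctx, watchdog_timeout=0.5, stray_rate=0.3,
                        rng=np.random.default_rng(3))

for tok in ["1", "2", "1", "9", "1", "2"]:
    link.send(tok, ctx.clock.now)
    ctx.clock.advance(0.2)

state = link.controller.state
print(f"pellet cycles: {state.pellet_cycles}  (one per '1' cue, strays ignored)")
print(f"tone on at t={ctx.clock.now:.1f}s: {tone_active(state, ctx.clock.now)}")

ctx.clock.advance(2.0)
watchdog_tick(state, ctx.clock.now, ctx)
print(f"tone on at t={ctx.clock.now:.1f}s: {tone_active(state, ctx.clock.now)} "
      "(expired; watchdog would also force off a stuck output)")

strays = [e for e in ctx.log if "stray_cue" in e.payload]
print(f"stray signals logged: {len(strays)}  (injected by the mock link + the '9')")
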