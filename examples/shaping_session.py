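"""Shape a naive simulated pig to criterion and inspect the stage ladder.

A subject that reliably presses the illuminated target advances through
the four shaping stages automatically — full-screen autoshaping, the
conditional full-screen stage, the 1/3-screen band, and the 40%-width
square — and is flagged ready for testing after the last threshold.
"""

from pigscreen import run_shaping_session, summarize_session

log, state = run_shaping_session("perfect", seed=7)

print(f"session complete: {state.complete}")
for ev in log:
    if ev.event_type == "stage_advance":
        print(f"  t={ev.timestamp:8.1f}s  stage_advance  {ev.payload}")

summary = summarize_session(log)
for key, value in summary.items():
    print(f"{key}: {value}")

print()
print("The four stage advances fall after 20, 15, 15 and 40 reinforced")
print("presses (90 trials total for a subject that never misses); each")
print("reinforced press triggered one pellet command to the dispenser.")
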