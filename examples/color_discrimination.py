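"""Color discrimination with correction trials and a conditional phase.

A noisy, green-biased chooser runs the yellow-vs-blue discrimination with
corrections, then the conditional (match-to-sample) phase where green or
blue in the center dictates the reinforced color — with an FR-3 on sample
and choice buttons. Correction trials re-present each error with the
wrong box disabled and never enter the accuracy denominator.
"""

from pigscreen import DiscriminationConfig, make_agent, run_discrimination_session, session_metrics

agent_kw = dict(color_bias=0.4, temperature=0.8, omission_prob=0.05)

for phase, extra in [("correction", {}), ("conditional", dict(fr_sample=3, fr_choice=3))]:
    config = DiscriminationConfig(phase=phase, **extra)
    log, state = run_discrimination_session(
        make_agent("biased", **agent_kw), config=config, n_trials=36, seed=4
    )
    m = session_metrics(log)
    corrections = state.trials_run - state.scored_trials
    print(f"phase={phase!r}  (fr_sample={config.fr_sample}, fr_choice={config.fr_choice})")
    print(f"  percent correct: {m.percent_correct:.1f}  (corrections run: {corrections})")
    print(f"  side bias (+1=left): {m.side_bias:+.2f}   "
          f"color bias (+1=green): {m.color_bias if m.color_bias is None else round(m.color_bias, 2)}")
    print(f"  omissions: {m.omissions}   mean initiation latency: "
          f"{m.mean_initiation_latency:.1f} s")

print()
print("The color index is green-vs-blue: in the yellow/blue correction")
print("phase the only green-or-blue choices are the blue errors, so it")
print("pins at -1. In the conditional phase the agent's green bias")
print("inflates green choices, which are reinforced only when the sample")
print("was green - accuracy sits near chance and corrections pile up.")
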