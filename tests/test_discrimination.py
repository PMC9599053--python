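"""Color discrimination: correction trials, conditional phase, fixed ratios."""

import numpy as np
import pytest

from pigscreen.agents import make_agent
from pigscreen.analysis import percent_correct, session_metrics
from pigscreen.core import ResponseBox, trials_from_log
from pigscreen.hal import make_peripherals
from pigscreen.session import run_discrimination_session
from pigscreen.tasks.common import balanced_side_sequence, fr_register
from pigscreen.tasks.discrimination import (
    DiscriminationConfig,
    DiscriminationState,
    correction_trial,
    make_discrimination_trial,
    run_discrimination_trial,
)

from conftest import make_ctx


class TestFixedRatio:
    def test_fr1_fulfils_on_first_press(self):
        box = ResponseBox("b", 0.3, 0.3, 0.2, 0.2)
        _, fulfilled = fr_register(box)
        assert fulfilled and box.fr_count == 0

    def test_fr3_fulfils_on_third_press_and_resets(self):
        box = ResponseBox("b", 0.3, 0.3, 0.2, 0.2, fr_requirement=3)
        assert fr_register(box)[1] is False
        assert fr_register(box)[1] is False
        assert fr_register(box)[1] is True
        assert box.fr_count == 0

    def test_fr3_seven_presses_fulfil_exactly_twice(self):
        box = ResponseBox("b", 0.3, 0.3, 0.2, 0.2, fr_requirement=3)
        fulfils = sum(fr_register(box)[1] for _ in range(7))
        assert fulfils == 2  # floor(7 / 3)

    def test_inactive_box_rejects_presses(self):
        box = ResponseBox("b", 0.3, 0.3, 0.2, 0.2, active=False, color="inactive_gray")
        with pytest.raises(ValueError):
            fr_register(box)


class TestSideSequence:
    def test_balanced_within_each_block(self, rng):
        sides = balanced_side_sequence(36, rng)
        for b in range(6):
            block = sides[b * 6 : (b + 1) * 6]
            assert block.count("left") == 3

    def test_run_length_capped_at_three(self, rng):
        sides = balanced_side_sequence(600, rng)
        run, prev = 0, None
        for s in sides:
            run = run + 1 if s == prev else 1
            prev = s
            assert run <= 3


class TestTrialSpecs:
    def test_simple_phase_targets_yellow_against_blue(self):
        spec = make_discrimination_trial(DiscriminationConfig(), 0, "left")
        correct = next(o for o in spec.options if o.is_correct)
        wrong = next(o for o in spec.options if not o.is_correct)
        assert correct.color == "yellow" and correct.side == "left"
        assert wrong.color == "blue" and wrong.side == "right"

    def test_conditional_phase_matches_the_sample_color(self, rng):
        cfg = DiscriminationConfig(phase="conditional")
        spec = make_discrimination_trial(cfg, 0, "right", rng)
        assert spec.sample_color in ("green", "blue")
        correct = next(o for o in spec.options if o.is_correct)
        assert correct.color == spec.sample_color

    def test_correction_preserves_layout_and_disables_the_error(self, rng):
        spec = make_discrimination_trial(DiscriminationConfig(phase="correction"), 0, "left")
        corr = correction_trial(spec)
        assert corr.trial_type == "correction"
        for orig, re_pres in zip(spec.options, corr.options):
            assert (orig.side, orig.color) == (re_pres.side, re_pres.color)
        active = [o for o in corr.options if o.active]
        assert len(active) == 1 and active[0].is_correct


def _run_session(agent, *, phase="correction", n_trials=24, seed=0, **cfg):
    config = DiscriminationConfig(phase=phase, **cfg)
    return run_discrimination_session(agent, config=config, n_trials=n_trials, seed=seed)


class TestTrialOutcomes:
    def test_correct_choice_is_reinforced(self):
        log, _ = _run_session(make_agent("perfect"), phase="simple", n_trials=6)
        trials = trials_from_log(log)
        assert all(t.choice == "correct" for t in trials)
        assert all(t.reinforcers_delivered == 1 for t in trials)

    def test_incorrect_choice_earns_nothing(self):
        # full blue bias in the simple phase: always the comparison color
        agent = make_agent("biased", color_bias=-1.0)
        log, _ = _run_session(agent, phase="simple", n_trials=6)
        trials = trials_from_log(log)
        assert all(t.choice == "incorrect" for t in trials)
        assert sum(t.reinforcers_delivered for t in trials) == 0

    def test_simple_phase_has_no_corrections(self):
        agent = make_agent("biased", color_bias=-1.0)
        log, _ = _run_session(agent, phase="simple", n_trials=6)
        assert not any(t.trial_type == "correction" for t in trials_from_log(log))

    def test_every_error_is_followed_by_its_correction(self):
        agent = make_agent("biased", color_bias=-0.2, temperature=0.8)
        log, _ = _run_session(agent, phase="correction", n_trials=24, seed=2)
        trials = trials_from_log(log)
        for prev, nxt in zip(trials, trials[1:]):
            if prev.trial_type != "correction" and prev.choice == "incorrect":
                assert nxt.trial_type == "correction"
                # identical layout: the correct side is unchanged
                assert nxt.choice_side == ("left" if prev.choice_side == "right" else "right")
                assert nxt.choice == "correct"  # the error is disabled

    def test_conditional_phase_reinforces_only_the_sample_color(self):
        agent = make_agent("biased", color_bias=1.0)  # always chooses green
        log, _ = _run_session(agent, phase="conditional", n_trials=24, seed=5)
        trials = [t for t in trials_from_log(log) if t.trial_type != "correction"]
        greens = [t for t in trials if t.choice_color == "green"]
        assert greens and all(t.choice_color == "green" for t in trials)
        # green is reinforced only when the sample was green (about half)
        correct = [t for t in trials if t.choice == "correct"]
        assert all(t.reinforcers_delivered == 1 for t in correct)
        incorrect = [t for t in trials if t.choice == "incorrect"]
        assert incorrect and all(t.reinforcers_delivered == 0 for t in incorrect)

    def test_fr3_requires_three_presses_on_sample_and_choice(self):
        log, _ = _run_session(
            make_agent("perfect"), phase="conditional", n_trials=4, fr_sample=3, fr_choice=3
        )
        presses = [e for e in log if e.event_type == "response_registered"]
        # 3 sample + 3 choice presses per trial
        assert len(presses) == 4 * 6
        fulfils = [e for e in presses if e.payload_dict.get("fulfilled") == "1"]
        assert len(fulfils) == 4 * 2


class TestAccuracy:
    def test_corrections_excluded_from_percent_correct(self):
        ctx = make_ctx("discrimination")
        link = make_peripherals(ctx)
        rng = np.random.default_rng(0)
        config = DiscriminationConfig(phase="correction")
        state = DiscriminationState(phase="correction")
        # alternate correct and incorrect planned choices
        good = make_agent("perfect")
        bad = make_agent("biased", color_bias=-1.0)
        idx = 0
        for i in range(12):
            agent = good if i % 2 == 0 else bad
            _, state = run_discrimination_trial(
                state, config, ctx, agent, link, rng, idx, correct_side="left"
            )
            idx += 1
            while state.pending_correction is not None:
                _, state = run_discrimination_trial(
                    state, config, ctx, good, link, rng, idx
                )
                idx += 1
        trials = trials_from_log(ctx.log)
        # 6 correct + 6 incorrect scored; 6 corrections excluded
        assert sum(t.trial_type == "correction" for t in trials) == 6
        assert percent_correct(trials) == pytest.approx(50.0)

    def test_perfect_agent_scores_100(self):
        log, _ = _run_session(make_agent("perfect"), phase="correction", n_trials=12)
        assert session_metrics(log).percent_correct == pytest.approx(100.0)
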