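"""Response shaping: stage geometry, thresholds, and autoshaping."""

import numpy as np
import pytest

from pigscreen.agents import make_agent
from pigscreen.hal import make_peripherals
from pigscreen.session import run_shaping_session
from pigscreen.tasks.shaping import (
    DEFAULT_THRESHOLDS,
    STAGE2_HEIGHTS,
    STAGE3_SIZE,
    ShapingConfig,
    ShapingState,
    autoshape_step,
    shaping_advance,
    shaping_geometry,
    shaping_press_step,
)

from conftest import make_ctx


class TestGeometry:
    def test_stage_1_is_the_full_screen(self, rng):
        g, _ = shaping_geometry(1, rng)
        b = g.boxes[0]
        assert (b.x, b.y, b.w, b.h) == (0.0, 0.0, 1.0, 1.0)
        assert b.color == "yellow"

    def test_stage_2_band_is_a_third_of_screen_height(self, rng):
        g, pos = shaping_geometry(2, rng)
        b = g.boxes[0]
        assert b.h == pytest.approx(1 / 3)
        assert b.w == 1.0
        assert b.y == pytest.approx(STAGE2_HEIGHTS[pos])

    def test_stage_3_square_is_40_percent_of_screen_width(self, rng):
        g, _ = shaping_geometry(3, rng)
        b = g.boxes[0]
        assert b.w == pytest.approx(0.40)
        assert b.h == pytest.approx(0.40)

    def test_stage_3_has_five_positions_all_on_screen(self, rng):
        seen = set()
        for _ in range(200):
            g, pos = shaping_geometry(3, rng)
            seen.add(pos)
            b = g.boxes[0]
            assert 0 <= b.x and b.x + b.w <= 1 and 0 <= b.y and b.y + b.h <= 1
        assert seen == {0, 1, 2, 3, 4}

    def test_stage_2_heights_drawn_uniformly(self, rng):
        from scipy import stats

        counts = np.zeros(3)
        for _ in range(3000):
            _, pos = shaping_geometry(2, rng)
            counts[pos] += 1
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.001

    def test_invalid_stage_rejected(self, rng):
        with pytest.raises(ValueError):
            shaping_geometry(7, rng)


class TestAdvance:
    def test_first_press_does_not_advance(self):
        state, advanced = shaping_advance(ShapingState(), ShapingConfig())
        assert (state.stage, state.presses_in_stage, advanced) == (0, 1, False)

    def test_twentieth_press_moves_to_stage_1(self):
        state = ShapingState(stage=0, presses_in_stage=19)
        state, advanced = shaping_advance(state, ShapingConfig())
        assert advanced and state.stage == 1 and state.presses_in_stage == 0

    def test_threshold_sequence_by_stepping_the_machine(self):
        # independent oracle: step press-by-press and record each boundary
        state, config = ShapingState(), ShapingConfig()
        boundaries = []
        presses = 0
        while not state.complete:
            state, advanced = shaping_advance(state, config)
            presses += 1
            if advanced:
                boundaries.append(presses)
        assert boundaries == [20, 35, 50, 90]  # cumulative sums of 20,15,15,40
        assert presses == sum(DEFAULT_THRESHOLDS)

    def test_stage_never_decreases(self):
        state, config = ShapingState(), ShapingConfig()
        last = 0
        while not state.complete:
            state, _ = shaping_advance(state, config)
            assert state.stage >= last
            last = state.stage

    def test_stage4_entered_when_enabled(self):
        config = ShapingConfig(stage4_enabled=True)
        state = ShapingState(stage=3, presses_in_stage=39)
        state, advanced = shaping_advance(state, config)
        assert advanced and state.stage == 4 and not state.complete


class TestAutoshape:
    def test_nonresponder_gets_pellet_exactly_10s_after_illumination(self):
        ctx = make_ctx("shaping")
        link = make_peripherals(ctx)
        agent = make_agent("nonresponder")
        start = ctx.clock.now
        result = autoshape_step(ShapingState(), ShapingConfig(), ctx, agent, link, 0)
        pellets = [e for e in ctx.log if e.event_type == "pellet_command"]
        assert len(pellets) == 1
        assert pellets[0].timestamp == pytest.approx(start + 10.0)
        assert pellets[0].payload_dict["noncontingent"] == "1"
        assert not result.omitted and result.reinforcers_delivered == 0

    def test_press_reinforced_immediately_and_cancels_pavlovian_delivery(self):
        ctx = make_ctx("shaping")
        link = make_peripherals(ctx)
        agent = make_agent("perfect", response_latency_mean=3.0, latency_sd=0.0)
        state = ShapingState()
        result = autoshape_step(state, ShapingConfig(), ctx, agent, link, 0)
        pellets = [e for e in ctx.log if e.event_type == "pellet_command"]
        assert len(pellets) == 1  # exactly one delivery per illumination
        assert pellets[0].timestamp == pytest.approx(3.0)
        assert "noncontingent" not in pellets[0].payload
        assert state.presses_in_stage == 1
        assert result.reinforcers_delivered == 1

    def test_slow_press_after_delay_is_not_reinforced_contingently(self):
        ctx = make_ctx("shaping")
        link = make_peripherals(ctx)
        agent = make_agent("perfect", response_latency_mean=12.0, latency_sd=0.0)
        state = ShapingState()
        autoshape_step(state, ShapingConfig(), ctx, agent, link, 0)
        assert state.presses_in_stage == 0  # Pavlovian pellet only


class TestPressStep:
    def test_omission_logged_when_agent_never_responds(self):
        ctx = make_ctx("shaping")
        link = make_peripherals(ctx)
        rng = np.random.default_rng(0)
        state = ShapingState(stage=2)
        result = shaping_press_step(state, ShapingConfig(), ctx, make_agent("nonresponder"),
                                    link, rng, 0)
        assert result.omitted
        assert any(e.event_type == "omission" for e in ctx.log)
        assert ctx.clock.now == pytest.approx(ShapingConfig().response_window_s)

    def test_stage4_square_shrinks_per_correct_trial(self):
        ctx = make_ctx("shaping")
        link = make_peripherals(ctx)
        rng = np.random.default_rng(0)
        config = ShapingConfig(stage4_enabled=True, stage4_decrement=0.05)
        state = ShapingState(stage=4, box_size=STAGE3_SIZE)
        agent = make_agent("perfect")
        sizes = [state.box_size]
        for i in range(4):
            shaping_press_step(state, config, ctx, agent, link, rng, i)
            sizes.append(state.box_size)
        assert sizes == pytest.approx([0.40, 0.35, 0.30, 0.25, 0.22])  # floored at minimum


class TestFullSession:
    def test_perfect_responder_completes_in_sum_of_thresholds(self):
        log, state = run_shaping_session("perfect", seed=11)
        assert state.complete
        advances = [e for e in log if e.event_type == "stage_advance"]
        assert len(advances) == 4
        contingent = [
            e for e in log
            if e.event_type == "pellet_command" and "noncontingent" not in e.payload
        ]
        assert len(contingent) == sum(DEFAULT_THRESHOLDS)

    def test_start_at_later_stage_skips_prerequisites(self):
        log, state = run_shaping_session(
            "perfect", config=ShapingConfig(start_stage=3), seed=11
        )
        assert state.complete
        pellets = [e for e in log if e.event_type == "pellet_command"]
        assert len(pellets) == DEFAULT_THRESHOLDS[3]

    def test_pellet_conservation_with_sloppy_agent(self):
        # scattered touches and omissions: pellets == contingent + noncontingent
        agent = make_agent("hyperbolic", touch_sd=0.1, swipe_offset=0.03, omission_prob=0.2)
        log, _ = run_shaping_session(agent, seed=3, max_trials=200)
        pellets = [e for e in log if e.event_type == "pellet_command"]
        reinforcement_n = sum(
            int(e.payload_dict["n"]) for e in log if e.event_type == "reinforcement"
        )
        noncontingent = [e for e in pellets if e.payload_dict.get("noncontingent") == "1"]
        assert len(pellets) == reinforcement_n + len(noncontingent)
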