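"""Task schedule and race-model simulation behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stoprace.sst_task import (
    ConfigurationError,
    RaceParams,
    build_schedule,
    default_schedule,
    simulate_participant,
    staircase_update,
    trials_to_frame,
)


@pytest.mark.parametrize(
    "blocks,tpb,rate,n_exp,n_stop",
    [(4, 24, 0.25, 96, 24), (1, 4, 0.25, 4, 1), (2, 24, 0.25, 48, 12)],
)
def test_schedule_counts(blocks, tpb, rate, n_exp, n_stop):
    sched = build_schedule(blocks, tpb, rate, seed=1)
    exp = sched.experimental_trials
    assert len(exp) == n_exp
    assert sum(t.is_stop for t in exp) == n_stop


def test_schedule_stop_count_exact_per_block():
    sched = build_schedule(4, 24, 0.25, seed=3)
    for b in range(1, 5):
        block = [t for t in sched.trials if t.block == b]
        assert sum(t.is_stop for t in block) == 6


def test_schedule_go_stimuli_balanced_within_block():
    sched = build_schedule(4, 24, 0.25, seed=9)
    for b in range(1, 5):
        syms = [t.go_stimulus for t in sched.trials if t.block == b]
        assert abs(syms.count("X") - syms.count("O")) <= 1


def test_schedule_seed_contract():
    a = build_schedule(2, 24, 0.25, seed=1)
    b = build_schedule(2, 24, 0.25, seed=2)
    stops_a = [t.trial for t in a.trials if t.is_stop]
    stops_b = [t.trial for t in b.trials if t.is_stop]
    assert len(stops_a) == len(stops_b) == 12
    assert stops_a != stops_b
    assert build_schedule(2, 24, 0.25, seed=1) == a  # deterministic


def test_schedule_nonintegral_stop_count_rejected():
    with pytest.raises(ConfigurationError):
        build_schedule(4, 10, 0.25, seed=0)


def test_practice_block_structure():
    sched = default_schedule(seed=0, include_practice=True)
    practice = [t for t in sched.trials if t.block == 0]
    assert len(practice) == 24
    assert sum(t.is_stop for t in practice) == 6
    assert sched.n_experimental == 96


@pytest.mark.parametrize(
    "ssd,inhibited,expected", [(250, True, 300), (250, False, 200), (0, False, 0)]
)
def test_staircase_examples(ssd, inhibited, expected):
    assert staircase_update(ssd, inhibited, 50, 0) == expected


def test_staircase_negative_step_rejected():
    with pytest.raises(ConfigurationError):
        staircase_update(250, True, -50, 0)


@given(
    ssd=st.floats(0, 1000),
    inhibited=st.booleans(),
    step=st.floats(0, 200),
    floor=st.floats(0, 100),
)
def test_staircase_properties(ssd, inhibited, step, floor):
    if ssd < floor:
        return
    out = staircase_update(ssd, inhibited, step, floor)
    assert out >= floor
    if inhibited:
        assert out == ssd + step
    else:
        assert out == max(ssd - step, floor)


def test_simulation_deterministic():
    sched = default_schedule(seed=5)
    p = RaceParams()
    a = simulate_participant(sched, p, seed=42)
    b = simulate_participant(sched, p, seed=42)
    assert a == b


def test_trial_record_invariants():
    sched = default_schedule(seed=5)
    recs = simulate_participant(sched, RaceParams(), seed=7)
    for r in recs:
        if r.is_stop:
            assert r.ssd is not None and r.ssd >= 0
        else:
            assert r.ssd is None
        if r.responded:
            assert r.rt is not None and r.rt <= 3000
            assert r.correct is not None
        else:
            assert r.rt is None and r.correct is None


def test_forced_race_outcomes():
    # Stop process far faster than go process: every stop trial inhibited.
    slow_go = RaceParams(go_mu=2000, go_sigma=1, go_tau=1, ssrt_mean=5, ssrt_sd=1,
                         go_omission_rate=0.0)
    recs = simulate_participant(default_schedule(seed=1), slow_go, seed=1)
    stops = [r for r in recs if r.is_stop]
    assert all(not r.responded for r in stops)
    # Go process far faster: every stop trial escapes (SSD floors at 0 but
    # stop finish 2000+ never beats a ~60 ms go finish).
    fast_go = RaceParams(go_mu=50, go_sigma=5, go_tau=5, ssrt_mean=2500, ssrt_sd=1,
                         go_omission_rate=0.0)
    recs = simulate_participant(default_schedule(seed=1), fast_go, seed=1)
    stops = [r for r in recs if r.is_stop]
    assert all(r.responded for r in stops)


def test_omission_rate_one_gives_no_responses():
    p = RaceParams(go_omission_rate=1.0)
    recs = simulate_participant(default_schedule(seed=2), p, seed=3)
    assert all(not r.responded for r in recs)


def test_staircase_tracks_half_inhibition():
    """Grand-mean p(inhibit) close to the 0.5 tracking target."""
    ps = []
    for i in range(300):
        recs = simulate_participant(default_schedule(seed=i), RaceParams(), seed=1000 + i)
        stops = [r for r in recs if r.is_stop and r.block > 0]
        ps.append(np.mean([not r.responded for r in stops]))
    assert abs(np.mean(ps) - 0.5) < 0.03


def test_terminal_ssd_compensates_for_stop_speed():
    """The staircase equilibrates where ssd + SSRT matches the go-finish
    quantile, so a slower stop process settles at a shorter delay (and the
    sum delay + stop latency is roughly conserved)."""

    def mean_final_ssd(ssrt_mean):
        finals = []
        for i in range(100):
            p = RaceParams(ssrt_mean=ssrt_mean)
            recs = simulate_participant(default_schedule(seed=i), p, seed=i)
            finals.append([r.ssd for r in recs if r.is_stop][-1])
        return np.mean(finals)

    slow, fast = mean_final_ssd(350.0), mean_final_ssd(200.0)
    assert slow < fast
    assert (slow + 350.0) == pytest.approx(fast + 200.0, abs=40)


def test_go_rt_unaffected_by_interleaved_stops():
    """Race independence: go-trial RTs don't depend on stop-trial presence."""
    no_stops = build_schedule(4, 24, 0.0, seed=1)
    with_stops = build_schedule(4, 24, 0.25, seed=1)
    p = RaceParams()
    rts_a, rts_b = [], []
    for i in range(200):
        a = simulate_participant(no_stops, p, seed=i)
        b = simulate_participant(with_stops, p, seed=i)
        rts_a += [r.rt for r in a if not r.is_stop and r.responded]
        rts_b += [r.rt for r in b if not r.is_stop and r.responded]
    assert abs(np.mean(rts_a) - np.mean(rts_b)) < 10


def test_trials_frame_layout():
    recs = simulate_participant(default_schedule(seed=0), RaceParams(), seed=0, participant_id="A1")
    fr = trials_to_frame(recs)
    assert list(fr.columns) == [
        "participant_id", "block", "trial", "is_stop", "ssd_ms", "responded", "correct", "rt_ms",
    ]
    assert (fr["participant_id"] == "A1").all()
    go_unresponded = fr[(fr["is_stop"] == 0) & (fr["responded"] == 0)]
    assert go_unresponded["rt_ms"].isna().all()
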