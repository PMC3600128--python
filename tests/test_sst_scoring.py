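"""Participant-level scoring: SSRT integration, filters, medication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stoprace.sst_scoring import (
    ParticipantSummary,
    UnscorableError,
    ValidityRule,
    adjust_for_medication,
    apply_validity_filters,
    exclusion_tally,
    integration_ssrt,
    score_cohort,
    score_trials,
    summarize_go,
)
from stoprace.sst_task import RaceParams, default_schedule, simulate_participant, trials_to_frame


def _trial_frame(go_rts, go_correct=None, stop_responded=(0, 1, 0, 1), ssd=250.0, pid="P"):
    rows = []
    go_correct = go_correct or [1] * len(go_rts)
    for i, (rt, c) in enumerate(zip(go_rts, go_correct)):
        rows.append(
            dict(participant_id=pid, block=1, trial=i, is_stop=0, ssd_ms=None,
                 responded=1, correct=c, rt_ms=rt)
        )
    for j, resp in enumerate(stop_responded):
        rows.append(
            dict(participant_id=pid, block=1, trial=len(go_rts) + j, is_stop=1,
                 ssd_ms=ssd, responded=resp, correct=1 if resp else None,
                 rt_ms=400.0 if resp else None)
        )
    return pd.DataFrame(rows)


def test_summarize_go_direct_arithmetic():
    acc, mean, sd = summarize_go([400, 500, 600], n_go_trials=3, n_correct=3)
    assert acc == 1.0 and mean == 500 and sd == 100


def test_summarize_go_counts_omissions_inaccurate():
    # 72 go trials, 48 correct responses, 24 omissions
    acc, _, _ = summarize_go([500.0] * 48, n_go_trials=72, n_correct=48)
    assert acc == pytest.approx(48 / 72)


def test_all_stop_trials_unscorable():
    fr = _trial_frame([], stop_responded=(0, 1))
    with pytest.raises(UnscorableError):
        score_trials(fr, expected_trials=None)


@pytest.mark.parametrize(
    "go_rts,p,ssd,expected",
    [
        ([300, 400, 500, 600, 700], 0.60, 200, 200),  # 2 fastest escape -> rank 2
        ([500] * 10, 0.5, 250, 250),  # degenerate distribution
    ],
)
def test_integration_ssrt_examples(go_rts, p, ssd, expected):
    assert integration_ssrt(go_rts, p, ssd) == expected


def test_integration_ssrt_matches_enumeration_oracle():
    """Brute-force over every rank of the 5-element list: the chosen RT must
    be the smallest order statistic at which the slower fraction >= p."""
    rts = sorted([300, 400, 500, 600, 700])
    for p in (0.2, 0.4, 0.6, 0.8):
        n = len(rts)
        oracle = None
        for k in range(1, n + 1):  # k-th smallest; slower fraction = 1 - k/n... pick by count
            n_escaping = k  # responses faster or equal would have escaped
            if n_escaping >= (1 - p) * n:
                oracle = rts[k - 1]
                break
        assert integration_ssrt(rts, p, 0.0) == oracle


@pytest.mark.parametrize("p", [0.0, 1.0])
def test_integration_ssrt_degenerate_p_raises(p):
    with pytest.raises(ValueError):
        integration_ssrt([400, 500], p, 200)


@given(
    shift=st.floats(-100, 100),
    p=st.floats(0.1, 0.9),
)
def test_integration_translation_equivariance(shift, p):
    rts = [310.0, 420.0, 480.0, 555.0, 610.0, 700.0]
    base = integration_ssrt(rts, p, 250.0)
    shifted_both = integration_ssrt([r + shift for r in rts], p, 250.0 + shift)
    shifted_rts = integration_ssrt([r + shift for r in rts], p, 250.0)
    assert shifted_both == pytest.approx(base, abs=1e-9)
    assert shifted_rts == pytest.approx(base + shift, abs=1e-9)


def test_integration_at_half_matches_mean_method():
    """At p(inhibit) = 0.5 the integration estimate approaches
    mean GoRT - mean SSD on large samples."""
    rng = np.random.default_rng(0)
    rts = rng.normal(600, 100, size=5001)
    est = integration_ssrt(rts, 0.5, 300.0)
    subtraction = rts.mean() - 300.0
    spacing = np.diff(np.sort(rts)).max()
    assert abs(est - subtraction) < max(5.0, spacing)


def _summary(acc=0.9, gort=600.0, p=0.5):
    return ParticipantSummary(
        participant_id="P", n_go=72, n_stop=24, go_accuracy=acc, gort_mean=gort,
        gort_sd=100.0, p_inhibit=p, mean_ssd=250.0, ssrt=300.0,
    )


@pytest.mark.parametrize(
    "acc,gort,p,strict,valid,reason",
    [
        (0.65, 600, 0.5, False, False, "accuracy"),
        (0.9, 99, 0.5, False, False, "gort"),
        (0.9, 600, 0.55, False, True, None),
        (0.9, 600, 0.55, True, True, None),
        (0.9, 600, 0.65, False, True, None),
        (0.9, 600, 0.65, True, False, "p_inhibit"),
        (0.9, 600, 0.19, False, False, "p_inhibit"),
        (0.9, 600, 0.81, False, False, "p_inhibit"),
        (0.66, 100, 0.20, False, True, None),  # thresholds are inclusive
    ],
)
def test_validity_filter_boundaries(acc, gort, p, strict, valid, reason):
    out = apply_validity_filters(_summary(acc, gort, p), ValidityRule(), strict=strict)
    assert out.valid == valid
    if reason:
        assert reason in out.exclusion_reasons


def test_filter_monotonicity_relaxing_never_invalidates():
    rule = ValidityRule()
    relaxed = ValidityRule(min_go_accuracy=0.5, min_gort=50.0, p_inhibit_bounds=(0.1, 0.9))
    for acc in (0.6, 0.7, 0.9):
        for p in (0.15, 0.3, 0.5, 0.85):
            s = _summary(acc=acc, p=p)
            if apply_validity_filters(s, rule).valid:
                assert apply_validity_filters(s, relaxed).valid


def test_strict_bounds_must_nest():
    with pytest.raises(ValueError):
        ValidityRule(p_inhibit_bounds=(0.45, 0.55), strict_p_inhibit_bounds=(0.4, 0.6))


@pytest.mark.parametrize(
    "ssrt,sd,med,es,expected",
    [(280, 100, True, 0.75, 355), (280, 100, False, 0.75, 280), (280, 100, True, 0.0, 280)],
)
def test_medication_adjustment(ssrt, sd, med, es, expected):
    assert adjust_for_medication(ssrt, sd, med, es) == expected


def test_medication_requires_positive_sd():
    with pytest.raises(ValueError):
        adjust_for_medication(280, 0.0, True)


def test_score_trials_end_to_end_fields():
    recs = simulate_participant(default_schedule(seed=1), RaceParams(), seed=1)
    s = score_trials(trials_to_frame(recs))
    assert s.n_go == 72 and s.n_stop == 24  # practice excluded
    assert 0 <= s.p_inhibit <= 1
    assert s.ssrt is not None and 0 < s.ssrt < 1000


def test_incomplete_session_flagged():
    recs = simulate_participant(default_schedule(seed=1), RaceParams(), seed=1)
    fr = trials_to_frame(recs).head(24 + 40)  # practice + 40 experimental
    s = apply_validity_filters(score_trials(fr))
    assert not s.complete
    assert not s.valid and "incomplete" in s.exclusion_reasons


def test_score_cohort_and_tally():
    frames = []
    for i in range(6):
        recs = simulate_participant(
            default_schedule(seed=i), RaceParams(), seed=i, participant_id=f"P{i}"
        )
        frames.append(trials_to_frame(recs))
    # one guessing profile that should fail the filters
    bad = simulate_participant(
        default_schedule(seed=99),
        RaceParams(go_mu=70, go_sigma=20, go_tau=20, go_error_rate=0.5),
        seed=99,
        participant_id="BAD",
    )
    frames.append(trials_to_frame(bad))
    summ = score_cohort(pd.concat(frames, ignore_index=True))
    assert len(summ) == 7
    tally = exclusion_tally(summ)
    total = int(tally.loc[tally["reason"] == "total_scored", "count"].iloc[0])
    n_any = int(tally.loc[tally["reason"] == "any_exclusion", "count"].iloc[0])
    assert total == 7
    assert n_any == int((~summ["valid"]).sum()) >= 1
    assert not summ.loc[summ["participant_id"] == "BAD", "valid"].iloc[0]
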