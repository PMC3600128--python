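"""Reduce trial-level SST records to per-participant statistics.

Computes go accuracy, go RT mean/SD (GoRT, GoRTSD), probability of inhibition,
mean stop-signal delay, and the integration-method SSRT; applies the validity
filters used for community samples (go accuracy >= 66%, GoRT >= 100 ms,
p(inhibit) within [0.20, 0.80], optionally the strict [0.40, 0.60] band); and
offers the stimulant-medication correction (+0.75 effect sizes, since
stimulants shorten SSRT and the correction estimates the untreated value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from collections import Counter

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantSummary",
    "ValidityRule",
    "UnscorableError",
    "summarize_go",
    "integration_ssrt",
    "score_trials",
    "apply_validity_filters",
    "adjust_for_medication",
    "score_cohort",
    "exclusion_tally",
]

# Exclusion reason codes.
REASON_ACCURACY = "accuracy"
REASON_GORT = "gort"
REASON_P_INHIBIT = "p_inhibit"
REASON_INCOMPLETE = "incomplete"
REASON_UNSCORABLE = "unscorable"


class UnscorableError(ValueError):
    """Participant has too little usable data to score."""


@dataclass(frozen=True)
class ValidityRule:
    """Validity thresholds; the strict inhibition band is nested inside the
    standard one."""

    min_go_accuracy: float = 0.66
    min_gort: float = 100.0
    p_inhibit_bounds: tuple[float, float] = (0.20, 0.80)
    strict_p_inhibit_bounds: tuple[float, float] = (0.40, 0.60)

    def __post_init__(self):
        lo, hi = self.p_inhibit_bounds
        slo, shi = self.strict_p_inhibit_bounds
        if not (lo <= slo <= shi <= hi):
            raise ValueError("strict inhibition bounds must nest inside standard bounds")


@dataclass
class ParticipantSummary:
    participant_id: str
    n_go: int
    n_stop: int
    go_accuracy: float
    gort_mean: float
    gort_sd: float
    p_inhibit: float
    mean_ssd: float
    ssrt: float | None
    complete: bool = True
    valid: bool = True
    exclusion_reasons: list[str] = field(default_factory=list)


def summarize_go(go_responded_correct_rts, n_go_trials, n_correct) -> tuple[float, float, float]:
    """Accuracy, mean and sample SD of go performance.

    Accuracy counts omissions as inaccurate (correct responses / all go
    trials); latency statistics cover responded-and-correct go trials.
    """
    rts = np.asarray(go_responded_correct_rts, dtype=float)
    if n_go_trials <= 0 or rts.size == 0:
        raise UnscorableError("no scorable go trials")
    accuracy = n_correct / n_go_trials
    mean = float(np.mean(rts))
    sd = float(np.std(rts, ddof=1)) if rts.size > 1 else 0.0
    return accuracy, mean, sd


def integration_ssrt(go_rts, p_inhibit: float, mean_ssd: float) -> float:
    """Integration-method SSRT.

    Go RTs on no-signal trials are rank-ordered ascending and the RT at rank
    ``ceil((1 - p_inhibit) * n)`` is taken: the faster fraction
    ``1 - p_inhibit`` of go responses would have escaped inhibition, all
    slower ones would have been stopped.  SSRT is that quantile minus the
    mean stop-signal delay.
    """
    rts = np.sort(np.asarray(go_rts, dtype=float))
    if rts.size == 0:
        raise UnscorableError("no go RTs available for integration")
    if not 0.0 < p_inhibit < 1.0:
        raise ValueError(
            "integration SSRT undefined at p_inhibit of 0 or 1 "
            "(such sessions fail the 0.20-0.80 inhibition filter)"
        )
    rank = math.ceil((1.0 - p_inhibit) * rts.size)  # 1-based
    rank = min(max(rank, 1), rts.size)
    return float(rts[rank - 1] - mean_ssd)


def score_trials(
    trials: pd.DataFrame,
    expected_trials: int | None = 96,
    include_practice: bool = False,
) -> ParticipantSummary:
    """Score one participant's trial frame (sst_task column layout).

    Practice trials (block 0) are dropped before scoring.  Sessions with
    fewer than ``expected_trials`` experimental trials are flagged incomplete.
    The RT ranking for the integration estimate uses all responded no-signal
    trials; accuracy and GoRT/GoRTSD use correct responses only.
    """
    pid = str(trials["participant_id"].iloc[0])
    if not include_practice:
        trials = trials[trials["block"] > 0]
    go = trials[trials["is_stop"] == 0]
    stop = trials[trials["is_stop"] == 1]
    n_go, n_stop = len(go), len(stop)
    complete = expected_trials is None or (n_go + n_stop) >= expected_trials

    go_resp = go[go["responded"] == 1]
    go_correct = go_resp[go_resp["correct"] == 1]
    if len(go_correct) == 0 or n_stop == 0:
        raise UnscorableError(f"participant {pid}: no scorable go/stop trials")

    accuracy, gort_mean, gort_sd = summarize_go(
        go_correct["rt_ms"].to_numpy(), n_go, len(go_correct)
    )
    p_inhibit = 1.0 - float(stop["responded"].mean())
    mean_ssd = float(stop["ssd_ms"].mean())
    if 0.0 < p_inhibit < 1.0:
        ssrt = integration_ssrt(go_resp["rt_ms"].to_numpy(), p_inhibit, mean_ssd)
    else:
        ssrt = None
    return ParticipantSummary(
        participant_id=pid,
        n_go=n_go,
        n_stop=n_stop,
        go_accuracy=accuracy,
        gort_mean=gort_mean,
        gort_sd=gort_sd,
        p_inhibit=p_inhibit,
        mean_ssd=mean_ssd,
        ssrt=ssrt,
        complete=complete,
    )


def apply_validity_filters(
    summary: ParticipantSummary,
    rule: ValidityRule = ValidityRule(),
    strict: bool = False,
) -> ParticipantSummary:
    """Mark a scored summary valid/invalid, accumulating reason codes."""
    reasons: list[str] = []
    if not summary.complete:
        reasons.append(REASON_INCOMPLETE)
    if summary.go_accuracy < rule.min_go_accuracy:
        reasons.append(REASON_ACCURACY)
    if summary.gort_mean < rule.min_gort:
        reasons.append(REASON_GORT)
    lo, hi = rule.strict_p_inhibit_bounds if strict else rule.p_inhibit_bounds
    if not lo <= summary.p_inhibit <= hi:
        reasons.append(REASON_P_INHIBIT)
    if summary.ssrt is None and REASON_P_INHIBIT not in reasons:
        reasons.append(REASON_UNSCORABLE)
    out = replace(summary)
    out.valid = len(reasons) == 0
    out.exclusion_reasons = reasons
    return out


def adjust_for_medication(
    ssrt: float,
    reference_sd: float,
    medicated: bool,
    effect_size: float = 0.75,
) -> float:
    """Correct a medicated participant's SSRT toward its untreated value.

    Stimulants shorten SSRT by about 0.75 standard deviations at moderate
    doses, so the estimated untreated value is ``ssrt + effect_size * sd``,
    with ``reference_sd`` the SSRT SD among unmedicated valid participants.
    """
    if reference_sd <= 0:
        raise ValueError("reference_sd must be positive")
    if not medicated:
        return ssrt
    return ssrt + effect_size * reference_sd


def score_cohort(
    trials: pd.DataFrame,
    rule: ValidityRule = ValidityRule(),
    strict: bool = False,
    expected_trials: int | None = 96,
) -> pd.DataFrame:
    """Score every participant in a multi-participant trial frame.

    Returns one row per participant with summary statistics, the validity
    flag and semicolon-joined reason codes; participants with no scorable
    trials at all appear with reason ``unscorable``.
    """
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        try:
            summ = score_trials(sub, expected_trials=expected_trials)
        except UnscorableError:
            rows.append(
                {
                    "participant_id": str(pid),
                    "n_go": int((sub["is_stop"] == 0).sum()),
                    "n_stop": int((sub["is_stop"] == 1).sum()),
                    "go_accuracy": np.nan,
                    "gort_mean": np.nan,
                    "gort_sd": np.nan,
                    "p_inhibit": np.nan,
                    "mean_ssd": np.nan,
                    "ssrt": np.nan,
                    "complete": False,
                    "valid": False,
                    "exclusion_reasons": REASON_UNSCORABLE,
                }
            )
            continue
        summ = apply_validity_filters(summ, rule, strict=strict)
        rows.append(
            {
                "participant_id": summ.participant_id,
                "n_go": summ.n_go,
                "n_stop": summ.n_stop,
                "go_accuracy": summ.go_accuracy,
                "gort_mean": summ.gort_mean,
                "gort_sd": summ.gort_sd,
                "p_inhibit": summ.p_inhibit,
                "mean_ssd": summ.mean_ssd,
                "ssrt": np.nan if summ.ssrt is None else summ.ssrt,
                "complete": summ.complete,
                "valid": summ.valid,
                "exclusion_reasons": ";".join(summ.exclusion_reasons),
            }
        )
    return pd.DataFrame(rows)


def exclusion_tally(summaries: pd.DataFrame) -> pd.DataFrame:
    """Counts per exclusion reason (a participant may carry several codes),
    plus totals — the exclusion-accounting report shape."""
    counter: Counter[str] = Counter()
    n_invalid = 0
    for reasons in summaries.loc[~summaries["valid"], "exclusion_reasons"]:
        n_invalid += 1
        for code in str(reasons).split(";"):
            if code:
                counter[code] += 1
    rows = [{"reason": k, "count": v} for k, v in sorted(counter.items())]
    rows.append({"reason": "any_exclusion", "count": n_invalid})
    rows.append({"reason": "total_scored", "count": len(summaries)})
    return pd.DataFrame(rows)
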