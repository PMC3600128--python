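"""End-to-end orchestration: generate -> simulate -> score -> model ->
heritability, with exclusion accounting and table-style reports.

A single master seed is threaded through stage-specific child seeds (spawned
via ``numpy.random.SeedSequence``) so a run is fully reproducible from its
configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .quantgen import Pedigree, bivariate_fit, univariate_h2
from .sst_scoring import ValidityRule, exclusion_tally, score_cohort
from .sst_task import default_schedule, simulate_participant, trials_to_frame
from .synthetic_cohort import (
    CohortSpec,
    apply_invalid_profile,
    generate_participants,
    traits_to_race_params,
)
from .trait_models import fit_trait_model, predict_grid

__all__ = ["RunConfig", "RunReport", "run", "simulate_cohort", "compare_groups"]


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    rule: ValidityRule = field(default_factory=ValidityRule)
    strict: bool = False
    seed: int = 0
    fit_models: bool = True
    fit_heritability: bool = True
    responses: tuple[str, ...] = ("ssrt", "gort_mean", "gort_sd")
    heritability_traits: tuple[str, ...] = ("swan_total", "ssrt", "gort_mean", "gort_sd")
    bivariate_pairs: tuple[tuple[str, str], ...] = (
        ("swan_total", "ssrt"),
        ("ssrt", "gort_sd"),
    )
    entry_alpha: float = 0.05
    output_dir: str | None = None


@dataclass
class RunReport:
    participants: pd.DataFrame
    summaries: pd.DataFrame
    cohort_table: pd.DataFrame
    exclusions: pd.DataFrame
    group_comparison: pd.DataFrame
    model_fits: dict
    prediction_grids: dict
    heritability: pd.DataFrame | None
    bivariate: pd.DataFrame | None
    provenance: dict


def _child_seeds(master: int, label: str, n: int = 1) -> np.ndarray:
    tag = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    return np.random.SeedSequence([master, tag]).generate_state(n)


def simulate_cohort(participants: pd.DataFrame, spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Simulate the full SST for every participant.

    Race parameters come from the trait-to-race maps (SWAN score, age, sex,
    latent channel residuals plus idiosyncratic noise); medicated individuals
    get multiplicatively shortened stop latencies; injected invalid profiles
    distort parameters or truncate sessions (quitters).
    """
    seeds = _child_seeds(seed, "simulate", 2 * len(participants) + 1)
    noise_rng = np.random.default_rng(seeds[-1])
    frames = []
    for i, row in enumerate(participants.itertuples(index=False)):
        z = {}
        for ch in ("ssrt", "gort", "gortsd"):
            m = spec.race_maps[ch]
            zval = getattr(row, f"latent_{ch}")
            if m.loading > 0 and m.noise_sd > 0:
                zval = zval + noise_rng.normal(0.0, m.noise_sd / m.loading)
            z[ch] = zval
        params = traits_to_race_params(row.swan_total, row.male, row.age, spec, z)
        if row.medicated:
            shorter = params.ssrt_mean * np.exp(-spec.medicated_log_shift)
            params = replace(params, ssrt_mean=shorter, ssrt_sd=max(0.2 * shorter, 10.0))
        if row.invalid_type not in ("none", "quitter"):
            params = apply_invalid_profile(params, row.invalid_type)
        schedule = default_schedule(seed=int(seeds[2 * i]), include_practice=True)
        records = simulate_participant(
            schedule, params, seed=int(seeds[2 * i + 1]), participant_id=row.individual_id
        )
        if row.invalid_type == "quitter" and row.max_trials > 0:
            keep = 24 + int(row.max_trials)  # practice + partial experimental
            records = records[:keep]
        frames.append(trials_to_frame(records))
    return pd.concat(frames, ignore_index=True)


def compare_groups(cohort_table: pd.DataFrame) -> pd.DataFrame:
    """Included-vs-excluded characteristics with two-sample tests
    (trait and age by Welch t, sex by chi-square on the 2x2 table)."""
    inc = cohort_table[cohort_table["included"]]
    exc = cohort_table[~cohort_table["included"]]
    rows = []
    for var in ("swan_total", "age"):
        a, b = inc[var].dropna(), exc[var].dropna()
        if len(b) > 1:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append(
            {
                "variable": var,
                "included_mean": float(a.mean()),
                "included_sd": float(a.std()),
                "excluded_mean": float(b.mean()) if len(b) else np.nan,
                "excluded_sd": float(b.std()) if len(b) > 1 else np.nan,
                "p_value": p,
            }
        )
    if len(exc):
        tab = np.array(
            [
                [int(inc["male"].sum()), int((1 - inc["male"]).sum())],
                [int(exc["male"].sum()), int((1 - exc["male"]).sum())],
            ]
        )
        p_sex = float(stats.chi2_contingency(tab)[1]) if tab.min() > 0 else np.nan
    else:
        p_sex = np.nan
    rows.append(
        {
            "variable": "male_pct",
            "included_mean": float(100 * inc["male"].mean()),
            "included_sd": np.nan,
            "excluded_mean": float(100 * exc["male"].mean()) if len(exc) else np.nan,
            "excluded_sd": np.nan,
            "p_value": p_sex,
        }
    )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; see module docstring."""
    t0 = time.time()
    spec = replace(config.cohort, seed=config.seed)
    participants = generate_participants(spec, seed=config.seed)
    trials = simulate_cohort(participants, spec, seed=config.seed)
    summaries = score_cohort(trials, rule=config.rule, strict=config.strict)

    cohort = participants.merge(
        summaries.rename(columns={"participant_id": "individual_id"}),
        on="individual_id",
        how="left",
    )
    cohort["included"] = cohort["valid"].fillna(False).astype(bool) & (
        cohort["medicated"] == 0
    )
    excl = exclusion_tally(summaries)
    n_med = int((cohort["medicated"] == 1).sum())
    excl = pd.concat(
        [excl, pd.DataFrame([{"reason": "medicated", "count": n_med}])],
        ignore_index=True,
    )
    comparison = compare_groups(cohort)

    model_fits: dict = {}
    grids: dict = {}
    if config.fit_models:
        fit_rows = cohort[cohort["included"]].rename(columns={"gort_mean": "gort_mean"})
        fit_rows = fit_rows.dropna(subset=["ssrt", "gort_mean", "gort_sd", "swan_total"])
        for resp in config.responses:
            forced = ("gort",) if resp == "gort_sd" else ()
            fit = fit_trait_model(
                fit_rows,
                response=resp,
                forced_terms=forced,
                entry_alpha=config.entry_alpha,
            )
            model_fits[resp] = fit
            grids[resp] = predict_grid(fit)

    herit = None
    biv = None
    if config.fit_heritability:
        included = cohort[cohort["included"]].set_index("individual_id")
        ped = Pedigree.from_frame(participants)
        covs = participants.set_index("individual_id")[["age", "male"]]
        covs = covs.reindex(ped.individuals)
        hrows = []
        for trait in config.heritability_traits:
            vals = included[trait].reindex(ped.individuals)
            est = univariate_h2(vals, ped, covariates=covs)
            hrows.append(
                {
                    "trait": trait,
                    "h2": est.h2,
                    "se": est.se,
                    "ci_low": est.ci[0],
                    "ci_high": est.ci[1],
                    "p_value": est.p_value,
                    "n_individuals": est.n_individuals,
                    "n_families": est.n_families,
                }
            )
        herit = pd.DataFrame(hrows)
        brows = []
        for t1, t2 in config.bivariate_pairs:
            est = bivariate_fit(
                included[t1].reindex(ped.individuals),
                included[t2].reindex(ped.individuals),
                ped,
                covariates=covs,
            )
            brows.append(
                {
                    "trait1": t1,
                    "trait2": t2,
                    "rhog": est.rhog,
                    "rhog_se": est.rhog_se,
                    "rhoe": est.rhoe,
                    "rhop": est.rhop,
                    "p_rhog_zero": est.p_rhog_zero,
                    "boundary": est.boundary,
                }
            )
        biv = pd.DataFrame(brows)

    provenance = {
        "seed": config.seed,
        "n_families": spec.n_families,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
        "config_hash": hashlib.sha256(
            json.dumps(
                {"seed": config.seed, "n_families": spec.n_families, "strict": config.strict},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:12],
    }
    report = RunReport(
        participants=participants,
        summaries=summaries,
        cohort_table=cohort,
        exclusions=excl,
        group_comparison=comparison,
        model_fits=model_fits,
        prediction_grids=grids,
        heritability=herit,
        bivariate=biv,
        provenance=provenance,
    )
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.participants.to_csv(outdir / "participants.csv", index=False)
    report.summaries.to_csv(outdir / "summaries.csv", index=False)
    report.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    report.group_comparison.to_csv(outdir / "group_comparison.csv", index=False)
    for resp, grid in report.prediction_grids.items():
        grid.to_csv(outdir / f"grid_{resp}.csv", index=False)
    if report.heritability is not None:
        report.heritability.to_csv(outdir / "heritability.csv", index=False)
    if report.bivariate is not None:
        report.bivariate.to_csv(outdir / "bivariate.csv", index=False)
    (outdir / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
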