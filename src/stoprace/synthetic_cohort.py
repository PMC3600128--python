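"""Synthetic family cohorts with controlled genetics and task parameters.

Generates sibling cohorts (families of 2-5 children, 6-18 years) with latent
traits built from an additive polygenic model: each trait is
``sqrt(h2) * g + sqrt(1 - h2) * e`` where the genetic part g is shared
between siblings with correlation 0.5 (a family factor and an individual
factor weighted sqrt(0.5) each) and cross-trait structure comes from genetic
(rhog) and environmental (rhoe) correlation matrices.  Latent ADHD trait is
expressed as an 18-item SWAN-style questionnaire score on the reversed scale
(-54..+54, higher = more ADHD traits); latent task traits shift the
race-model parameters so that higher ADHD traits produce longer SSRT, slower
go responses and greater response variability, with both improving with age.

The trait-to-race maps are log-linear and calibrated against a published
predicted-value grid so the simulated SSRT gradient from trait -54 to +54 at
age 6 is roughly 140 ms and shrinks with age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantgen import Pedigree
from .sst_task import RaceParams

__all__ = [
    "CohortSpec",
    "RaceMap",
    "generate_pedigree",
    "generate_traits",
    "generate_swan",
    "traits_to_race_params",
    "generate_participants",
    "apply_invalid_profile",
]

TRAITS = ("adhd", "ssrt", "gort", "gortsd")

# Default genetic correlations among latent traits (upper triangle).
DEFAULT_RHOG = {
    ("adhd", "ssrt"): 0.18,
    ("adhd", "gort"): -0.12,
    ("adhd", "gortsd"): 0.05,
    ("ssrt", "gort"): -0.11,
    ("ssrt", "gortsd"): 0.42,
    ("gort", "gortsd"): 0.71,
}
DEFAULT_RHOE = {
    ("adhd", "ssrt"): 0.10,
    ("adhd", "gort"): 0.00,
    ("adhd", "gortsd"): 0.05,
    ("ssrt", "gort"): 0.10,
    ("ssrt", "gortsd"): 0.20,
    ("gort", "gortsd"): 0.50,
}


@dataclass(frozen=True)
class RaceMap:
    """Log-linear map from (trait score, age, sex, latent residual) to one
    race-model quantity: ``log q = intercept + b_trait*trait + b_age*age +
    (male0 + male_age*age)*male + loading*z``."""

    intercept: float
    b_trait: float
    b_age: float
    male0: float
    male_age: float
    loading: float = 0.0
    noise_sd: float = 0.0

    def log_value(self, trait: float, age: float, male: float, z: float = 0.0) -> float:
        return (
            self.intercept
            + self.b_trait * trait
            + self.b_age * age
            + (self.male0 + self.male_age * age) * male
            + self.loading * z
        )


def _default_race_maps() -> dict[str, RaceMap]:
    # Calibrated against the reference grid: e.g. exp maps give a ~138 ms
    # SSRT difference between trait -54 and +54 for girls at age 6, shrinking
    # multiplicatively with age, and male/female convergence by age 18.
    return {
        "ssrt": RaceMap(6.5410, 0.002764, -0.06754, -0.10562, 0.005867, 0.30, 0.15),
        "gort": RaceMap(6.7919, 0.000370, -0.02867, -0.09485, 0.006008, 0.12, 0.06),
        "gortsd": RaceMap(5.7103, 0.002057, -0.04604, -0.13415, 0.007925, 0.20, 0.08),
    }


@dataclass
class CohortSpec:
    """Study-condition parameters for cohort generation.

    Defaults mirror the community family cohort that motivates the package:
    family-size proportions 3081:387:35:4 for 2-5 children, ages 6-18,
    49.9% male, trait heritabilities 0.38/0.31/0.26/0.28, SWAN total mean
    -5.8 and SD 16.3 on the reversed scale, 2.6% medicated.
    """

    n_families: int = 200
    family_size_weights: dict[int, float] = field(
        default_factory=lambda: {2: 3081, 3: 387, 4: 35, 5: 4}
    )
    age_range: tuple[float, float] = (6.0, 18.0)
    sex_ratio_male: float = 0.499
    traits: tuple[str, ...] = TRAITS
    h2: dict[str, float] = field(
        default_factory=lambda: {"adhd": 0.38, "ssrt": 0.31, "gort": 0.26, "gortsd": 0.28}
    )
    rhog: dict[tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_RHOG))
    rhoe: dict[tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_RHOE))
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    swan_mean: float = -5.8
    swan_sd: float = 16.3
    swan_item_sd: float = 0.9
    swan_male_shift: float = 3.0
    race_maps: dict[str, RaceMap] = field(default_factory=_default_race_maps)
    medicated_rate: float = 0.026
    medicated_log_shift: float = 0.2625  # 0.75 x typical log-SSRT dispersion
    invalid_rate: float = 0.05
    seed: int = 0

    def corr_matrix(self, which: str) -> np.ndarray:
        """Assemble the rhog/rhoe trait-pair map into a full matrix."""
        pairs = self.rhog if which == "rhog" else self.rhoe
        t = list(self.traits)
        M = np.eye(len(t))
        for (a, b), r in pairs.items():
            if a in t and b in t:
                i, j = t.index(a), t.index(b)
                M[i, j] = M[j, i] = r
        return M

    def validate(self) -> None:
        if any(w < 0 for w in self.family_size_weights.values()):
            raise ValueError("family size weights must be non-negative")
        for tr, h in self.h2.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"h2[{tr}] outside [0, 1]")
        for which in ("rhog", "rhoe"):
            M = self.corr_matrix(which)
            w, v = np.linalg.eigh(M)
            if w.min() < -1e-8:
                vec = np.abs(v[:, int(np.argmin(w))])
                worst = [self.traits[i] for i in np.argsort(vec)[-2:]]
                raise ValueError(
                    f"{which} matrix not positive semi-definite "
                    f"(offending pair: {worst[1]}-{worst[0]})"
                )


def generate_pedigree(spec: CohortSpec, seed: int | None = None):
    """Draw family sizes, ages and sexes; returns (Pedigree, covariates).

    Covariates frame has individual_id, family_id, age (uniform in range,
    0.1-year resolution) and male flag; row order matches
    ``pedigree.individuals``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sizes = np.array(sorted(spec.family_size_weights))
    w = np.array([spec.family_size_weights[s] for s in sizes], dtype=float)
    w /= w.sum()
    fam_sizes = rng.choice(sizes, size=spec.n_families, p=w)

    rows = []
    fams = []
    for f, n in enumerate(fam_sizes):
        fid = f"F{f:05d}"
        members = tuple(f"{fid}_{k}" for k in range(n))
        fams.append((fid, members))
        for m in members:
            rows.append(
                {
                    "individual_id": m,
                    "family_id": fid,
                    "age": round(float(rng.uniform(*spec.age_range)), 1),
                    "male": int(rng.random() < spec.sex_ratio_male),
                }
            )
    return Pedigree(families=tuple(fams)), pd.DataFrame(rows)


def generate_traits(
    pedigree: Pedigree, spec: CohortSpec, covariates: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Latent unit-variance trait phenotypes with sibling genetic correlation
    exactly 0.5 per trait.

    Genetic values per family combine a shared and an individual factor with
    weights sqrt(0.5); cross-trait structure follows the cohort spec's
    rhog/rhoe matrices; configured covariate effects (columns of
    ``covariates``) are added to the mean.
    """
    spec.validate()
    rng = np.random.default_rng((spec.seed + 7919) if seed is None else seed)
    t = list(spec.traits)
    Rg = spec.corr_matrix("rhog")
    Re = spec.corr_matrix("rhoe")
    jitter = 1e-10 * np.eye(len(t))
    Lg = np.linalg.cholesky(Rg + jitter)
    Le = np.linalg.cholesky(Re + jitter)
    h = np.array([spec.h2[x] for x in t])
    sqh = np.sqrt(h)
    sqe = np.sqrt(1.0 - h)

    out = np.empty((pedigree.n_individuals, len(t)))
    pos = 0
    for _, members in pedigree.families:
        n = len(members)
        g_shared = Lg @ rng.standard_normal(len(t))
        g_ind = rng.standard_normal((n, len(t))) @ Lg.T
        g = np.sqrt(0.5) * (g_shared[None, :] + g_ind)
        e = rng.standard_normal((n, len(t))) @ Le.T
        out[pos : pos + n] = sqh * g + sqe * e
        pos += n

    frame = pd.DataFrame(out, columns=t)
    frame.insert(0, "individual_id", pedigree.individuals)
    if spec.covariate_effects and covariates is not None:
        cov = covariates.set_index("individual_id").loc[frame["individual_id"]]
        for trait, slopes in spec.covariate_effects.items():
            for col, b in slopes.items():
                frame[trait] = frame[trait].to_numpy() + b * cov[col].to_numpy()
    return frame


def generate_swan(
    latent, spec: CohortSpec, male=None, seed: int | None = None
) -> pd.DataFrame:
    """SWAN-style questionnaire scores from latent ADHD trait values.

    Each of 18 items is a discretized shifted normal clipped to the 7-point
    scale; scores are emitted on the reversed (analysis) scale where +3 per
    item / +54 total is maximal ADHD traits.  Totals equal the sum of the
    9-item inattention and hyperactivity-impulsivity subscales by
    construction.  The item scale is chosen so the population total matches
    the configured mean/SD including item noise.
    """
    rng = np.random.default_rng((spec.seed + 104729) if seed is None else seed)
    z = np.asarray(latent, dtype=float)
    n = z.shape[0]
    item_noise_var = spec.swan_item_sd**2 + 1.0 / 12.0
    scale = np.sqrt(max(spec.swan_sd**2 - 18.0 * item_noise_var, 0.0))
    center = spec.swan_mean + scale * z
    if male is not None:
        center = center + spec.swan_male_shift * (np.asarray(male, dtype=float) - 0.5)
    per_item = center / 18.0
    items = rng.normal(per_item[:, None], spec.swan_item_sd, size=(n, 18))
    items = np.clip(np.rint(items), -3, 3).astype(int)
    ia = items[:, :9].sum(axis=1)
    hi = items[:, 9:].sum(axis=1)
    return pd.DataFrame(
        {
            "swan_inattention": ia,
            "swan_hyperimpulsive": hi,
            "swan_total": ia + hi,
        }
    )


def traits_to_race_params(
    trait_value: float,
    male: int | float,
    age: float,
    spec: CohortSpec | None = None,
    z: dict[str, float] | None = None,
) -> RaceParams:
    """Deterministic map from trait score and demographics to race
    parameters.

    ``trait_value`` is on the reversed SWAN scale (-54..+54).  ``z`` carries
    optional latent residuals per channel (ssrt/gort/gortsd) that flow in
    through the map loadings; with zero slopes and no residuals all
    individuals share identical parameters.  Monotone: higher trait lengthens
    ssrt_mean and go latency parameters; older age shortens them.
    """
    spec = spec or CohortSpec()
    z = z or {}
    maps = spec.race_maps
    ssrt_mean = float(np.exp(maps["ssrt"].log_value(trait_value, age, male, z.get("ssrt", 0.0))))
    gort_target = float(np.exp(maps["gort"].log_value(trait_value, age, male, z.get("gort", 0.0))))
    gortsd_target = float(
        np.exp(maps["gortsd"].log_value(trait_value, age, male, z.get("gortsd", 0.0)))
    )
    tau = max(0.8 * gortsd_target, 10.0)
    sigma = max(0.6 * gortsd_target, 5.0)
    mu = max(gort_target - tau, 60.0)
    return RaceParams(
        go_mu=mu,
        go_sigma=sigma,
        go_tau=tau,
        ssrt_mean=max(ssrt_mean, 30.0),
        ssrt_sd=max(0.2 * ssrt_mean, 10.0),
    )


INVALID_TYPES = ("guesser", "quitter", "erratic")


def apply_invalid_profile(params: RaceParams, invalid_type: str) -> RaceParams:
    """Race-parameter distortions for injected invalid performers.

    Guessers respond near-randomly and far too fast (fails the 100 ms GoRT
    and 66% accuracy screens); erratic responders make many errors and
    omissions; quitters keep normal parameters but their sessions are
    truncated by the simulator.
    """
    if invalid_type == "guesser":
        return replace(params, go_mu=70.0, go_sigma=25.0, go_tau=30.0, go_error_rate=0.5)
    if invalid_type == "erratic":
        return replace(params, go_error_rate=0.45, go_omission_rate=0.20)
    if invalid_type == "quitter":
        return params
    raise ValueError(f"unknown invalid profile {invalid_type!r}")


def generate_participants(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Full participant table: pedigree, demographics, latent traits, SWAN
    scores, medication and injected-invalidity flags.

    Medication probability rises with ADHD trait (treated children have
    higher traits); invalid performance is biased toward younger,
    higher-trait males, mirroring the exclusion patterns such cohorts show.
    Returns one row per individual; race parameters are derived downstream
    via :func:`traits_to_race_params`.
    """
    spec.validate()
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed + 424243)
    pedigree, cov = generate_pedigree(spec, seed=base_seed)
    latent = generate_traits(pedigree, spec, covariates=cov, seed=base_seed + 1)
    swan = generate_swan(
        latent["adhd"].to_numpy(), spec, male=cov["male"].to_numpy(), seed=base_seed + 2
    )
    table = pd.concat([cov.reset_index(drop=True), swan], axis=1)
    for tr in spec.traits:
        table[f"latent_{tr}"] = latent[tr].to_numpy()

    n = len(table)
    trait = table["swan_total"].to_numpy(dtype=float)
    # Medication: mean rate spec.medicated_rate, odds rising with trait.
    wmed = np.exp(0.04 * (trait - trait.mean()))
    pmed = np.clip(spec.medicated_rate * wmed / wmed.mean(), 0, 1)
    table["medicated"] = (rng.random(n) < pmed).astype(int)

    # Invalid performers: younger, higher-trait, male-skewed.
    winv = np.exp(
        0.02 * (trait - trait.mean())
        + 0.12 * (12.0 - table["age"].to_numpy())
        + 0.3 * table["male"].to_numpy()
    )
    pinv = np.clip(spec.invalid_rate * winv / winv.mean(), 0, 1)
    is_invalid = rng.random(n) < pinv
    types = rng.choice(INVALID_TYPES, size=n)
    table["invalid_type"] = np.where(is_invalid, types, "none")
    # Quitters stop after 30-70 of the 96 experimental trials.
    table["max_trials"] = np.where(
        table["invalid_type"] == "quitter", rng.integers(30, 71, size=n), 0
    )
    return table
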