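"""Synthetic stroke-cohort generation.

Real multi-center stroke MRI cohorts of this kind are available only on
request, so the pipeline is exercised on simulated cohorts that emulate
the published marginal structure:

* constellation-category shares (≈49.7% single lesion, 37.4% multiple
  lesions in one territory, the remainder spread over multi-territory
  patterns);
* MCA-dominant territory involvement weights;
* log-normal total DWI lesion volume per group, calibrated so the
  simulated median/IQR match the printed group medians and IQRs
  (single: 1.7 ml, IQR 11.2; multiple: 7.7 ml, IQR 30.4), and likewise
  for WMH burden (6.1/14.4 vs 5.3/11.3 ml);
* outcome-generating models NIHSS = α_g + β_g·ln V + Normal(0, σ)
  (rounded and clipped to 0–42) and logit P(mRS > 2) = α_g + β_g·ln V,
  with stratum-specific severity slopes echoing the published anterior
  (≈1.56 for both groups) and posterior (≈0.21 single vs 0.39 multiple)
  circulation estimates;
* baseline covariate prevalences per group, and completely-at-random
  missingness that reproduces the published severity (~41% retained) and
  outcome (~30% retained) subset proportions.

In addition, :func:`plant_fixture` builds small cohorts whose classifier
and tabulator outputs hit requested counts *exactly* — used for worked
examples and arithmetic checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from mal_profiler.errors import InfeasibleFixtureError, ValidationError
from mal_profiler.territories import COUNT_COLUMNS, TERRITORY_ORDER, Territory

#: z-score of the 75th percentile; Q3/Q1 of a log-normal sit at exp(±z·σ).
_Z75 = stats.norm.ppf(0.75)

CLINICAL_COLUMNS = (
    "age", "sex", "htn", "dm", "af", "cad", "smoker", "etiology",
    "nihss", "mrs", "dwi_vol_ml", "wmh_vol_ml", "lacunar",
)
COHORT_COLUMNS = ("patient_id",) + COUNT_COLUMNS + CLINICAL_COLUMNS


def solve_lognormal_scale(median: float, iqr: float) -> float:
    """Scale σ of a log-normal with location ln(median) and the given IQR.

    For LogNormal(ln m, σ) the quartiles are m·exp(±z₀.₇₅σ), so the IQR is
    2·m·sinh(z₀.₇₅σ). σ is found numerically (Brent root bracketing) to
    |IQR error| < 1e-6.
    """
    if median <= 0 or iqr <= 0:
        raise ValidationError("median and iqr must be positive")

    def f(sigma):
        return 2.0 * median * math.sinh(_Z75 * sigma) - iqr

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValidationError("could not bracket log-normal scale")
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

#: patients per territory (single+multiple column masses of the published
#: per-territory table); used as involvement weights.
DEFAULT_TERRITORY_WEIGHTS: dict[Territory, float] = {
    Territory.ACA_LEFT: 39, Territory.ACA_RIGHT: 44,
    Territory.MCA_LEFT: 945, Territory.MCA_RIGHT: 849,
    Territory.PCA_LEFT: 217, Territory.PCA_RIGHT: 195,
    Territory.CEREBELLUM_LEFT: 174, Territory.CEREBELLUM_RIGHT: 182,
    Territory.BRAINSTEM: 337,
}


def _default_category_shares() -> dict[str, float]:
    return {
        "single_in_one": 0.497,
        "multiple_in_one": 0.374,
        "two_singles": 0.032,
        "single_plus_multiple": 0.041,
        "two_multiples": 0.056,
    }


def _default_volume_models() -> dict[str, dict[str, float]]:
    return {
        "single": {"median": 1.7, "iqr": 11.2},
        "multiple": {"median": 7.7, "iqr": 30.4},
    }


def _default_wmh_models() -> dict[str, dict[str, float]]:
    return {
        "single": {"median": 6.1, "iqr": 14.4},
        "multiple": {"median": 5.3, "iqr": 11.3},
    }


def _default_nihss_models() -> dict[str, dict[str, float]]:
    # alpha_* chosen so group mean NIHSS lands near the published 4.6 / 6.3
    # given the group's median log-volume; betas echo the published
    # stratum-specific posterior means.
    return {
        "anterior": {
            "alpha_single": 3.8, "alpha_multiple": 3.1,
            "beta_single": 1.56, "beta_multiple": 1.57, "sigma": 4.0,
        },
        "posterior": {
            "alpha_single": 3.5, "alpha_multiple": 3.5,
            "beta_single": 0.21, "beta_multiple": 0.39, "sigma": 4.0,
        },
    }


def _default_mrs_model() -> dict[str, float]:
    # equal slopes by default: the published difference distribution for the
    # functional outcome was centred at ~0
    return {
        "alpha_single": -1.5, "alpha_multiple": -1.5,
        "beta_single": 0.35, "beta_multiple": 0.35,
    }


def _default_covariates() -> dict[str, dict[str, float]]:
    return {
        "htn": {"single": 0.666, "multiple": 0.642},
        "dm": {"single": 0.242, "multiple": 0.230},
        "af": {"single": 0.124, "multiple": 0.169},
        "cad": {"single": 0.169, "multiple": 0.180},
        "smoker": {"single": 0.433, "multiple": 0.442},
    }


def _default_etiology() -> dict[str, dict[str, float]]:
    return {
        "single": {
            "cardioembolic": 0.137, "large_artery": 0.160,
            "small_vessel": 0.260, "other": 0.057, "undetermined": 0.386,
        },
        "multiple": {
            "cardioembolic": 0.181, "large_artery": 0.301,
            "small_vessel": 0.040, "other": 0.086, "undetermined": 0.392,
        },
    }


@dataclass
class GeneratorConfig:
    """All distributional parameters of the cohort simulator.

    Defaults emulate the published cohort's marginal structure; every
    field can be overridden, e.g. to plant known outcome-model slopes for
    recovery studies.
    """

    n_patients: int = 2466
    seed: int = 0
    category_shares: dict[str, float] = field(default_factory=_default_category_shares)
    territory_weights: dict[Territory, float] = field(
        default_factory=lambda: dict(DEFAULT_TERRITORY_WEIGHTS)
    )
    extra_lesion_rate: float = 0.8  # count in a "multiple" territory = 2 + Poisson(rate)
    volume_models: dict[str, dict[str, float]] = field(default_factory=_default_volume_models)
    wmh_models: dict[str, dict[str, float]] = field(default_factory=_default_wmh_models)
    nihss_models: dict[str, dict[str, float]] = field(default_factory=_default_nihss_models)
    mrs_model: dict[str, float] = field(default_factory=_default_mrs_model)
    covariates: dict[str, dict[str, float]] = field(default_factory=_default_covariates)
    etiology_shares: dict[str, dict[str, float]] = field(default_factory=_default_etiology)
    age_mean: float = 63.4
    age_sd: float = 14.8
    age_range: tuple[float, float] = (18.0, 100.0)
    p_female: float = 0.390
    # retained fractions match the published severity / outcome subsets
    p_missing_severity: float = 0.59  # masks dwi_vol_ml and nihss jointly
    p_missing_mrs: float = 0.697
    lacunar_fraction: float = 0.149
    lacunar_volume_ml: float = 1.77  # sphere of 1.5 cm diameter
    log_epsilon: float = 0.01

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_patients < 0:
            bad.append("n_patients")
        shares = self.category_shares
        if any(not 0.0 <= v <= 1.0 for v in shares.values()):
            bad.append("category_shares (values outside [0,1])")
        elif abs(sum(shares.values()) - 1.0) > 1e-9:
            bad.append("category_shares (must sum to 1)")
        for p in ("p_female", "p_missing_severity", "p_missing_mrs", "lacunar_fraction"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                bad.append(p)
        for grp, m in self.volume_models.items():
            if m["median"] <= 0 or m["iqr"] <= 0:
                bad.append(f"volume_models[{grp}]")
        for grp, m in self.wmh_models.items():
            if m["median"] <= 0 or m["iqr"] <= 0:
                bad.append(f"wmh_models[{grp}]")
        for grp, shares_ in self.etiology_shares.items():
            if abs(sum(shares_.values()) - 1.0) > 1e-9:
                bad.append(f"etiology_shares[{grp}]")
        if any(w < 0 for w in self.territory_weights.values()):
            bad.append("territory_weights")
        if bad:
            raise ValidationError("invalid generator config fields: " + ", ".join(bad))


def sample_dwi_volumes(group: str, n: int, seed_or_rng, config: GeneratorConfig | None = None) -> np.ndarray:
    """Draw n total DWI lesion volumes (ml) from one group's calibrated model."""
    config = config or GeneratorConfig()
    if group not in config.volume_models:
        raise ValidationError(f"unknown group {group!r}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    m = config.volume_models[group]
    sigma = solve_lognormal_scale(m["median"], m["iqr"])
    return rng.lognormal(mean=math.log(m["median"]), sigma=sigma, size=n)


_CATEGORY_STATUSES = {
    "single_in_one": ("single",),
    "multiple_in_one": ("multiple",),
    "two_singles": ("single", "single"),
    "single_plus_multiple": ("single", "multiple"),
    "two_multiples": ("multiple", "multiple"),
}


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort; reproducible under a fixed (config, seed) pair.

    Returns a frame in the cohort schema (territory counts + clinical
    columns). ``seed`` overrides ``config.seed`` when given.
    """
    config = config or GeneratorConfig()
    config.validate()
    n = config.n_patients
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if n == 0:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))

    cat_names = list(config.category_shares)
    cat_p = np.array([config.category_shares[c] for c in cat_names])
    categories = rng.choice(len(cat_names), size=n, p=cat_p)

    terr_list = list(TERRITORY_ORDER)
    w = np.array([config.territory_weights.get(t, 0.0) for t in terr_list], dtype=float)
    if w.sum() <= 0:
        raise ValidationError("territory weights must have positive total mass")
    w = w / w.sum()

    counts = np.zeros((n, 9), dtype=int)
    mal = np.zeros(n, dtype=bool)
    circulation = np.empty(n, dtype=object)
    supra_single = np.zeros(n, dtype=bool)  # single lesion in one supratentorial territory
    for i in range(n):
        statuses = _CATEGORY_STATUSES[cat_names[categories[i]]]
        k = len(statuses)
        idx = rng.choice(9, size=k, replace=False, p=w)
        total = 0
        for j, status in zip(idx, statuses):
            c = 1 if status == "single" else 2 + rng.poisson(config.extra_lesion_rate)
            counts[i, j] = c
            total += c
        mal[i] = total > 1
        circs = {terr_list[j].circulation for j in idx}
        circulation[i] = "both" if len(circs) == 2 else next(iter(circs))
        supra_single[i] = (
            total == 1 and terr_list[idx[0]].compartment == "supratentorial"
        )

    group = np.where(mal, "multiple", "single")

    # volumes -----------------------------------------------------------
    dwi = np.empty(n)
    wmh = np.empty(n)
    for grp in ("single", "multiple"):
        mask = group == grp
        vm, wm = config.volume_models[grp], config.wmh_models[grp]
        dwi[mask] = rng.lognormal(
            math.log(vm["median"]), solve_lognormal_scale(vm["median"], vm["iqr"]), mask.sum()
        )
        wmh[mask] = rng.lognormal(
            math.log(wm["median"]), solve_lognormal_scale(wm["median"], wm["iqr"]), mask.sum()
        )
    logv = np.log(np.clip(dwi, config.log_epsilon, None))

    # outcomes ----------------------------------------------------------
    # patients spanning both circulations follow the anterior model
    stratum = np.where(circulation == "posterior", "posterior", "anterior")
    nihss = np.empty(n)
    for strat, m in config.nihss_models.items():
        for grp in ("single", "multiple"):
            mask = (stratum == strat) & (group == grp)
            mu = m[f"alpha_{grp}"] + m[f"beta_{grp}"] * logv[mask]
            nihss[mask] = mu + rng.normal(0.0, m["sigma"], mask.sum())
    nihss = np.clip(np.round(nihss), 0, 42)

    mm = config.mrs_model
    alpha = np.where(mal, mm["alpha_multiple"], mm["alpha_single"])
    beta = np.where(mal, mm["beta_multiple"], mm["beta_single"])
    p_unfav = expit(alpha + beta * logv)
    unfav = rng.random(n) < p_unfav
    mrs = np.where(
        unfav,
        rng.choice([3, 4, 5, 6], size=n, p=[0.45, 0.25, 0.15, 0.15]),
        rng.choice([0, 1, 2], size=n, p=[0.25, 0.35, 0.40]),
    )

    # covariates --------------------------------------------------------
    a, b = config.age_range
    age = stats.truncnorm.rvs(
        (a - config.age_mean) / config.age_sd, (b - config.age_mean) / config.age_sd,
        loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng,
    )
    sex = (rng.random(n) < config.p_female).astype(int)
    flags = {}
    for name, prev in config.covariates.items():
        p = np.where(mal, prev["multiple"], prev["single"])
        flags[name] = (rng.random(n) < p).astype(int)
    etiology = np.empty(n, dtype=object)
    for grp in ("single", "multiple"):
        mask = group == grp
        levels = list(config.etiology_shares[grp])
        probs = np.array([config.etiology_shares[grp][lv] for lv in levels])
        etiology[mask] = rng.choice(levels, size=mask.sum(), p=probs)

    # lacunar flag: structurally eligible single small supratentorial
    # lesions, thinned by the configured subcortical fraction
    eligible = supra_single & (dwi < config.lacunar_volume_ml)
    lacunar = (eligible & (rng.random(n) < config.lacunar_fraction)).astype(int)

    # missingness (MCAR) ------------------------------------------------
    miss_sev = rng.random(n) < config.p_missing_severity
    miss_mrs = rng.random(n) < config.p_missing_mrs
    dwi_out = np.where(miss_sev, np.nan, np.round(dwi, 4))
    wmh_out = np.round(wmh, 4)
    nihss_out = np.where(miss_sev, np.nan, nihss)
    mrs_out = np.where(miss_mrs, np.nan, mrs.astype(float))

    frame = pd.DataFrame({"patient_id": [f"P{i:06d}" for i in range(n)]})
    for j, t in enumerate(TERRITORY_ORDER):
        frame[t.column] = counts[:, j]
    frame["age"] = np.round(age, 1)
    frame["sex"] = sex
    for name in ("htn", "dm", "af", "cad", "smoker"):
        frame[name] = flags[name]
    frame["etiology"] = etiology
    frame["nihss"] = nihss_out
    frame["mrs"] = mrs_out
    frame["dwi_vol_ml"] = dwi_out
    frame["wmh_vol_ml"] = wmh_out
    frame["lacunar"] = lacunar
    return frame


# ---------------------------------------------------------------------------
# exact-count fixture planting
# ---------------------------------------------------------------------------

# territory pairs realizing every (bilateral, supra+infra, ant+post) combo
_PAIR_FOR_FLAGS: dict[tuple[bool, bool, bool], tuple[Territory, Territory]] = {
    (True, True, True): (Territory.MCA_LEFT, Territory.CEREBELLUM_RIGHT),
    (True, True, False): (Territory.PCA_LEFT, Territory.CEREBELLUM_RIGHT),
    (True, False, True): (Territory.MCA_LEFT, Territory.PCA_RIGHT),
    (False, True, True): (Territory.MCA_LEFT, Territory.BRAINSTEM),
    (True, False, False): (Territory.MCA_LEFT, Territory.MCA_RIGHT),
    (False, True, False): (Territory.PCA_LEFT, Territory.CEREBELLUM_LEFT),
    (False, False, True): (Territory.MCA_LEFT, Territory.PCA_LEFT),
    (False, False, False): (Territory.MCA_LEFT, Territory.ACA_LEFT),
}


@dataclass
class FixtureSpec:
    """Exact counts a planted cohort must reproduce.

    ``categories`` maps category keys (``single_in_one``,
    ``multiple_in_one``, ``two_singles``, ``single_plus_multiple``,
    ``two_multiples``) to patient counts. ``flags`` may request exact
    ``bilateral``, ``supra_and_infra`` and ``ant_and_post`` totals, all of
    which are realized among the multi-territory patients.
    ``territory_cells`` maps a territory to an exact
    (n_single_here, n_multiple_here) pair, realized with one-territory
    patients appended to the cohort.
    """

    categories: dict[str, int] = field(default_factory=dict)
    flags: dict[str, int] = field(default_factory=dict)
    territory_cells: dict[Territory, tuple[int, int]] = field(default_factory=dict)


def _flag_assignment(b: int, si: int, ap: int, n_multi: int) -> list[tuple[bool, bool, bool]]:
    """Assign flag triples to multi-territory patients hitting exact totals."""
    for name, v in (("bilateral", b), ("supra_and_infra", si), ("ant_and_post", ap)):
        if v < 0:
            raise InfeasibleFixtureError(f"negative flag count for {name}")
    triples: list[tuple[bool, bool, bool]] = []
    g = min(b, si, ap)
    triples += [(True, True, True)] * g
    rb, rsi, rap = b - g, si - g, ap - g
    # after removing the triple overlap at most two remainders are nonzero;
    # overlap those two, then place the rest alone
    if rb and rsi:
        k = min(rb, rsi)
        triples += [(True, True, False)] * k
        rb, rsi = rb - k, rsi - k
    if rb and rap:
        k = min(rb, rap)
        triples += [(True, False, True)] * k
        rb, rap = rb - k, rap - k
    if rsi and rap:
        k = min(rsi, rap)
        triples += [(False, True, True)] * k
        rsi, rap = rsi - k, rap - k
    triples += [(True, False, False)] * rb
    triples += [(False, True, False)] * rsi
    triples += [(False, False, True)] * rap
    if len(triples) > n_multi:
        raise InfeasibleFixtureError(
            f"flag counts (bilateral={b}, supra_and_infra={si}, ant_and_post={ap}) "
            f"need {len(triples)} multi-territory patients but only {n_multi} requested"
        )
    triples += [(False, False, False)] * (n_multi - len(triples))
    return triples


def plant_fixture(spec: FixtureSpec) -> pd.DataFrame:
    """Build a cohort whose classify/tabulate outputs hit the requested counts exactly."""
    unknown = set(spec.categories) - set(_CATEGORY_STATUSES)
    if unknown:
        raise InfeasibleFixtureError(f"unknown category keys: {sorted(unknown)}")
    unknown = set(spec.flags) - {"bilateral", "supra_and_infra", "ant_and_post"}
    if unknown:
        raise InfeasibleFixtureError(f"unknown flag keys: {sorted(unknown)}")
    if any(v < 0 for v in spec.categories.values()):
        raise InfeasibleFixtureError("negative category count")

    rows: list[dict[str, int]] = []

    # one-territory patients
    rows += [{Territory.MCA_LEFT.column: 1}] * spec.categories.get("single_in_one", 0)
    rows += [{Territory.MCA_LEFT.column: 2}] * spec.categories.get("multiple_in_one", 0)

    # multi-territory patients: counts by category, territory pair by flags
    count_pairs: list[tuple[int, int]] = (
        [(1, 1)] * spec.categories.get("two_singles", 0)
        + [(1, 2)] * spec.categories.get("single_plus_multiple", 0)
        + [(2, 2)] * spec.categories.get("two_multiples", 0)
    )
    triples = _flag_assignment(
        spec.flags.get("bilateral", 0),
        spec.flags.get("supra_and_infra", 0),
        spec.flags.get("ant_and_post", 0),
        len(count_pairs),
    )
    for (c1, c2), flags in zip(count_pairs, triples):
        t1, t2 = _PAIR_FOR_FLAGS[flags]
        rows.append({t1.column: c1, t2.column: c2})

    # exact per-territory single/multiple cells
    for terr, (n_single, n_multiple) in spec.territory_cells.items():
        if n_single < 0 or n_multiple < 0:
            raise InfeasibleFixtureError(f"negative cell count for {terr}")
        rows += [{terr.column: 1}] * n_single
        rows += [{terr.column: 2}] * n_multiple

    frame = pd.DataFrame(
        [{col: r.get(col, 0) for col in COUNT_COLUMNS} for r in rows], dtype=int
    )
    frame.insert(0, "patient_id", [f"F{i:06d}" for i in range(len(frame))])
    return frame
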