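"""Bayesian hierarchical regression of stroke outcomes on log lesion volume.

The scientific question: does total acute (DWI) lesion volume relate to
stroke severity (NIHSS) or to unfavorable functional outcome (mRS > 2)
differently for patients with a single versus multiple acute lesions?

Model (linear case)::

    y_i ~ Normal(alpha_{g(i)} + beta_{g(i)} * log V_i, sigma)
    alpha_g ~ Normal(mu_alpha, tau_alpha)      g in {single, multiple}
    beta_g  ~ Normal(mu_beta,  tau_beta)
    mu_*    ~ Normal(0, 10),  tau_* ~ HalfNormal(10),  sigma ~ HalfNormal(10)

and analogously with a Bernoulli likelihood and logit link for the
dichotomized functional outcome. The hierarchical structure yields the
volume effect separately per group *within one model*, so the group
estimates can be compared draw-wise: the difference distribution
(single − multiple) is summarized by its mean and 90% highest posterior
density interval (HPDI), and the group difference is called *substantial*
exactly when that HPDI excludes zero.

Posterior sampling
------------------
The linear model is sampled by block Gibbs: the per-group
(intercept, slope) pair has a conjugate bivariate-normal full conditional
given the hyperparameters and sigma, the hyper-means are conjugate
normals, and the scale parameters (tau_alpha, tau_beta, sigma) are updated
by 1-D slice sampling on the log scale. The logistic model replaces the
conjugate group block with an independence Metropolis–Hastings update
whose proposal is a Student-t built from the group's Laplace (penalized
maximum-likelihood) approximation; hyperparameters are updated as in the
linear case. Both samplers run several independent chains; convergence is
monitored by rank-normalized split R-hat across chains and a fit whose
max R-hat exceeds the threshold is flagged, never silently accepted.

Strata: the cohort can be restricted to anterior-circulation-only or
posterior-circulation-only patients. Patients spanning both circulations
are excluded from either stratum, and lacunar-stroke patients (a single
small subcortical supratentorial lesion) are excluded from the anterior
stratum by default, because the lacunar definition precludes multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from mal_profiler.errors import (
    InsufficientDataError,
    NonIdentifiableError,
    SeparationError,
    ValidationError,
)

_LOG_2PI = np.log(2.0 * np.pi)
# bounds for log-scale slice updates; keep degenerate (zero-variance)
# outcomes from driving sigma/tau to an improper spike at zero
_LOG_SCALE_LO = -7.0
_LOG_SCALE_HI = 7.0


@dataclass(frozen=True)
class HierModelSpec:
    """Model, prior and sampler settings for one hierarchical fit."""

    outcome_kind: str = "linear"  # linear | logistic
    outcome: str = "nihss"
    predictor: str = "dwi_vol_ml"  # natural-log-transformed internally
    group: str = "mal"  # False = single, True = multiple
    hyper_loc_scale: float = 10.0  # prior sd of mu_alpha, mu_beta
    hyper_tau_scale: float = 10.0  # half-normal scale of tau_alpha, tau_beta
    sigma_scale: float = 10.0  # half-normal scale of residual sd (linear)
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000  # per chain
    seed: int = 0
    hpdi_mass: float = 0.90
    log_epsilon: float = 0.01  # ml; floor for the log transform
    rhat_threshold: float = 1.01
    min_group_n: int = 10

    def __post_init__(self):
        if self.outcome_kind not in ("linear", "logistic"):
            raise ValidationError(f"unknown outcome_kind: {self.outcome_kind}")
        if not 0.0 < self.hpdi_mass < 1.0:
            raise ValidationError("hpdi_mass must lie in (0, 1)")
        for name in ("hyper_loc_scale", "hyper_tau_scale", "sigma_scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.chains < 2:
            raise ValidationError("at least 2 chains are required for R-hat")


@dataclass(frozen=True)
class StratumSpec:
    """Circulation stratum and lacunar handling.

    ``exclude_lacunar=None`` resolves to the protocol default: lacunar
    patients are dropped from the anterior stratum and kept elsewhere.
    Pass an explicit boolean to override.
    """

    circulation: str = "all"  # all | anterior | posterior
    exclude_lacunar: bool | None = None

    def __post_init__(self):
        if self.circulation not in ("all", "anterior", "posterior"):
            raise ValidationError(f"unknown circulation stratum: {self.circulation}")

    @property
    def lacunar_excluded(self) -> bool:
        if self.exclude_lacunar is None:
            return self.circulation == "anterior"
        return self.exclude_lacunar


@dataclass(frozen=True)
class PosteriorSummary:
    """Mean and HPDI of one scalar posterior."""

    mean: float
    hpdi_low: float
    hpdi_high: float
    mass: float
    n_draws: int


@dataclass
class InteractionResult:
    """Per-group slope posteriors, their difference, and the verdict."""

    slope_single: PosteriorSummary
    slope_multiple: PosteriorSummary
    difference: PosteriorSummary  # single - multiple, draw-wise
    substantial: bool
    intercept_single: PosteriorSummary
    intercept_multiple: PosteriorSummary
    n_single: int
    n_multiple: int
    diagnostics: dict = field(default_factory=dict)
    draws: dict = field(default_factory=dict)  # raw aligned draws for audit

    @property
    def usable(self) -> bool:
        return bool(self.diagnostics.get("converged", False))


def hpdi(draws, mass: float) -> tuple[float, float]:
    """Shortest contiguous window over the sorted draws holding >= mass.

    The window spans ``ceil(mass * n)`` order statistics; among windows of
    equal width the lowest one is returned.
    """
    d = np.sort(np.asarray(draws, dtype=float))
    if d.size < 2:
        raise InsufficientDataError("hpdi needs at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise ValidationError("hpdi mass must lie in (0, 1)")
    m = max(int(np.ceil(mass * d.size)), 1)
    widths = d[m - 1 :] - d[: d.size - m + 1]
    i = int(np.argmin(widths))  # first minimal window
    return float(d[i]), float(d[i + m - 1])


def summarize_posterior(draws, mass: float) -> PosteriorSummary:
    d = np.asarray(draws, dtype=float)
    low, high = hpdi(d, mass)
    return PosteriorSummary(
        mean=float(np.mean(d)), hpdi_low=low, hpdi_high=high, mass=mass, n_draws=d.size
    )


def difference_distribution(a, b, mass: float = 0.90) -> tuple[PosteriorSummary, bool]:
    """Draw-wise difference a − b with HPDI summary and substantiality flag.

    Draws must come aligned from the same fitted model (equal counts, same
    chain/draw order). ``substantial`` is True iff the HPDI excludes zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"draw counts differ ({a.shape} vs {b.shape}); difference draws must be aligned"
        )
    diff = a - b
    summary = summarize_posterior(diff, mass)
    substantial = not (summary.hpdi_low <= 0.0 <= summary.hpdi_high)
    return summary, substantial


def stratify_cohort(cohort: pd.DataFrame, spec: StratumSpec) -> pd.DataFrame:
    """Restrict a labelled cohort to one circulation stratum.

    Anterior stratum: all lesions within ACA/MCA territories. Posterior:
    all within PCA/cerebellum/brainstem. Patients with lesions in both
    circulations belong to neither stratum. Lacunar patients are removed
    per :class:`StratumSpec`.
    """
    if "circulation" not in cohort.columns:
        raise ValidationError("cohort must be labelled (run label_cohort first)")
    out = cohort
    if spec.circulation != "all":
        out = out[out["circulation"] == spec.circulation]
    if spec.lacunar_excluded:
        if "lacunar" not in out.columns:
            raise ValidationError("lacunar exclusion requested but no 'lacunar' column")
        out = out[out["lacunar"].fillna(0).astype(int) == 0]
    return out.copy()


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _slice_update(logf, x0: float, rng, w: float = 1.0,
                  lo: float = _LOG_SCALE_LO, hi: float = _LOG_SCALE_HI) -> float:
    """One stepping-out + shrinkage slice-sampling update (Neal 2003)."""
    logy = logf(x0) - rng.exponential()
    u = rng.uniform(0.0, w)
    left, right = x0 - u, x0 + u
    while left > lo and logf(left) > logy:
        left -= w
    while right < hi and logf(right) > logy:
        right += w
    left, right = max(left, lo), min(right, hi)
    while True:
        x1 = rng.uniform(left, right)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _sample_bivariate(prec: np.ndarray, h: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^-1 h, prec^-1) for a 2x2 precision matrix."""
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, h)
    z = rng.standard_normal(2)
    return mean + np.linalg.solve(chol.T, z)


def _log_tau_conditional(s_sq: float, hyper_scale: float):
    # p(tau | groups, mu) ∝ tau^-G exp(-S/(2 tau^2)) HalfNormal(tau; scale),
    # G = 2 groups; expressed over u = log tau including the Jacobian
    def logf(u):
        tau_sq = np.exp(2.0 * u)
        return -2.0 * u - 0.5 * s_sq / tau_sq - 0.5 * tau_sq / hyper_scale**2 + u

    return logf


class _LinearGibbs:
    """Block-Gibbs sampler for the hierarchical linear model.

    Works entirely on per-group sufficient statistics, so one scan is O(1)
    in the sample size.
    """

    def __init__(self, x_s, y_s, x_m, y_m, spec: HierModelSpec):
        self.spec = spec
        self.stats = []
        for x, y in ((x_s, y_s), (x_m, y_m)):
            self.stats.append(
                dict(
                    n=len(x), sx=float(np.sum(x)), sxx=float(np.sum(x * x)),
                    sy=float(np.sum(y)), sxy=float(np.sum(x * y)), syy=float(np.sum(y * y)),
                )
            )
        self.n_total = self.stats[0]["n"] + self.stats[1]["n"]

    def _ssr(self, g: int, a: float, b: float) -> float:
        s = self.stats[g]
        return (
            s["syy"] - 2.0 * a * s["sy"] - 2.0 * b * s["sxy"]
            + a * a * s["n"] + 2.0 * a * b * s["sx"] + b * b * s["sxx"]
        )

    def init_state(self, rng) -> dict:
        coefs = []
        for s in self.stats:
            # per-group least squares from sufficient statistics
            det = s["n"] * s["sxx"] - s["sx"] ** 2
            b = (s["n"] * s["sxy"] - s["sx"] * s["sy"]) / det
            a = (s["sy"] - b * s["sx"]) / s["n"]
            coefs.append((a, b))
        ssr = sum(self._ssr(g, *coefs[g]) for g in (0, 1))
        sigma = max(np.sqrt(max(ssr, 1e-10) / self.n_total), 1e-3)
        state = dict(
            ab=[list(c) for c in coefs],
            mu_a=0.5 * (coefs[0][0] + coefs[1][0]),
            mu_b=0.5 * (coefs[0][1] + coefs[1][1]),
            log_tau_a=0.0, log_tau_b=0.0, log_sigma=float(np.log(sigma)),
        )
        # overdisperse chains mildly around the least-squares start
        for g in (0, 1):
            state["ab"][g][0] += 0.1 * rng.standard_normal()
            state["ab"][g][1] += 0.1 * rng.standard_normal()
        state["log_sigma"] += 0.05 * rng.standard_normal()
        return state

    def scan(self, state: dict, rng) -> None:
        spec = self.spec
        sigma_sq = np.exp(2.0 * state["log_sigma"])
        tau_a_sq = np.exp(2.0 * state["log_tau_a"])
        tau_b_sq = np.exp(2.0 * state["log_tau_b"])

        # group (intercept, slope) blocks: conjugate bivariate normal
        for g in (0, 1):
            s = self.stats[g]
            prec = np.array(
                [
                    [s["n"] / sigma_sq + 1.0 / tau_a_sq, s["sx"] / sigma_sq],
                    [s["sx"] / sigma_sq, s["sxx"] / sigma_sq + 1.0 / tau_b_sq],
                ]
            )
            h = np.array(
                [
                    s["sy"] / sigma_sq + state["mu_a"] / tau_a_sq,
                    s["sxy"] / sigma_sq + state["mu_b"] / tau_b_sq,
                ]
            )
            state["ab"][g] = list(_sample_bivariate(prec, h, rng))

        # hyper-means: conjugate normal given group effects and tau
        for key, tau_sq, idx in (("mu_a", tau_a_sq, 0), ("mu_b", tau_b_sq, 1)):
            total = state["ab"][0][idx] + state["ab"][1][idx]
            prec = 2.0 / tau_sq + 1.0 / spec.hyper_loc_scale**2
            state[key] = rng.normal((total / tau_sq) / prec, 1.0 / np.sqrt(prec))

        # hyper-scales and residual sd: slice updates on the log scale
        for key, idx, mu in (("log_tau_a", 0, state["mu_a"]), ("log_tau_b", 1, state["mu_b"])):
            s_sq = sum((state["ab"][g][idx] - mu) ** 2 for g in (0, 1))
            state[key] = _slice_update(
                _log_tau_conditional(s_sq, spec.hyper_tau_scale), state[key], rng
            )

        ssr = sum(self._ssr(g, *state["ab"][g]) for g in (0, 1))

        def log_sigma_cond(u):
            sig_sq = np.exp(2.0 * u)
            return (
                -self.n_total * u - 0.5 * ssr / sig_sq
                - 0.5 * sig_sq / spec.sigma_scale**2 + u
            )

        state["log_sigma"] = _slice_update(log_sigma_cond, state["log_sigma"], rng)

    def record(self, state: dict) -> tuple:
        return (
            state["ab"][0][0], state["ab"][1][0],
            state["ab"][0][1], state["ab"][1][1],
            np.exp(state["log_sigma"]),
        )


class _LogisticMwG:
    """Metropolis-within-Gibbs sampler for the hierarchical logistic model.

    Group (intercept, slope) blocks are updated by independence MH with a
    fixed Student-t proposal centred on the group's maximum-likelihood
    estimate (Laplace approximation); hyperparameters are updated exactly
    as in the linear sampler.
    """

    _PROPOSAL_DF = 10.0
    _PROPOSAL_INFLATE = 1.2  # widen the Laplace covariance for robustness

    def __init__(self, x_s, y_s, x_m, y_m, spec: HierModelSpec):
        self.spec = spec
        self.data = [(x_s, y_s), (x_m, y_m)]
        self.proposals = []
        for x, y in self.data:
            center, cov = self._laplace(x, y)
            shape = cov * self._PROPOSAL_INFLATE
            chol = np.linalg.cholesky(shape)
            self.proposals.append((center, chol, np.linalg.inv(shape)))
        self.accepts = np.zeros(2)
        self.attempts = np.zeros(2)

    def _propose(self, g: int, rng) -> np.ndarray:
        center, chol, _ = self.proposals[g]
        z = rng.standard_normal(2)
        scale = np.sqrt(self._PROPOSAL_DF / rng.chisquare(self._PROPOSAL_DF))
        return center + scale * (chol @ z)

    def _proposal_logpdf(self, g: int, theta: np.ndarray) -> float:
        # bivariate Student-t log-density up to an additive constant
        center, _, shape_inv = self.proposals[g]
        d = theta - center
        q = float(d @ shape_inv @ d)
        return -0.5 * (self._PROPOSAL_DF + 2.0) * np.log1p(q / self._PROPOSAL_DF)

    @staticmethod
    def _laplace(x, y):
        import statsmodels.api as sm

        X = np.column_stack([np.ones_like(x), x])
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            return np.asarray(fit.params, dtype=float), np.asarray(fit.cov_params(), dtype=float)
        except Exception:
            return np.zeros(2), np.eye(2)

    def _loglik(self, g: int, a: float, b: float) -> float:
        x, y = self.data[g]
        eta = a + b * x
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def init_state(self, rng) -> dict:
        starts = [list(center + 0.1 * rng.standard_normal(2)) for center, _, _ in self.proposals]
        return dict(
            ab=starts,
            mu_a=0.5 * (starts[0][0] + starts[1][0]),
            mu_b=0.5 * (starts[0][1] + starts[1][1]),
            log_tau_a=0.0, log_tau_b=0.0,
        )

    def scan(self, state: dict, rng) -> None:
        spec = self.spec
        tau_a = np.exp(state["log_tau_a"])
        tau_b = np.exp(state["log_tau_b"])

        for g in (0, 1):
            theta0 = np.asarray(state["ab"][g], dtype=float)
            theta1 = self._propose(g, rng)

            def log_target(theta):
                a, b = theta
                return (
                    self._loglik(g, a, b)
                    - 0.5 * ((a - state["mu_a"]) / tau_a) ** 2
                    - 0.5 * ((b - state["mu_b"]) / tau_b) ** 2
                )

            log_accept = (
                log_target(theta1) - log_target(theta0)
                + self._proposal_logpdf(g, theta0) - self._proposal_logpdf(g, theta1)
            )
            self.attempts[g] += 1
            if np.log(rng.random()) < log_accept:
                state["ab"][g] = [float(theta1[0]), float(theta1[1])]
                self.accepts[g] += 1

        for key, tau_sq, idx in (("mu_a", tau_a**2, 0), ("mu_b", tau_b**2, 1)):
            total = state["ab"][0][idx] + state["ab"][1][idx]
            prec = 2.0 / tau_sq + 1.0 / spec.hyper_loc_scale**2
            state[key] = rng.normal((total / tau_sq) / prec, 1.0 / np.sqrt(prec))

        for key, idx, mu in (("log_tau_a", 0, state["mu_a"]), ("log_tau_b", 1, state["mu_b"])):
            s_sq = sum((state["ab"][g][idx] - mu) ** 2 for g in (0, 1))
            state[key] = _slice_update(
                _log_tau_conditional(s_sq, spec.hyper_tau_scale), state[key], rng
            )

    def record(self, state: dict) -> tuple:
        return (
            state["ab"][0][0], state["ab"][1][0],
            state["ab"][0][1], state["ab"][1][1],
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _group_arrays(data: pd.DataFrame, spec: HierModelSpec, binary_outcome: bool):
    for col in (spec.outcome, spec.predictor, spec.group):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from model input")
    d = data[[spec.outcome, spec.predictor, spec.group]].dropna()
    grp = d[spec.group].astype(bool)
    out = {}
    for name, mask in (("single", ~grp), ("multiple", grp)):
        sub = d[mask]
        n = len(sub)
        if n < spec.min_group_n:
            raise InsufficientDataError(
                f"{name} group has {n} complete rows; at least {spec.min_group_n} required"
            )
        v = sub[spec.predictor].to_numpy(dtype=float)
        if np.any(v < 0):
            raise ValidationError("negative lesion volume encountered")
        x = np.log(np.clip(v, spec.log_epsilon, None))
        y = sub[spec.outcome].to_numpy(dtype=float)
        if np.var(x) == 0.0:
            raise NonIdentifiableError(
                f"log-volume predictor is constant in the {name} group"
            )
        if binary_outcome:
            classes = np.unique(y)
            if not np.all(np.isin(classes, (0.0, 1.0))):
                raise ValidationError("logistic outcome must be coded 0/1")
            if classes.size < 2:
                raise SeparationError(
                    f"outcome is single-class in the {name} group; slope not identifiable"
                )
        out[name] = (x, y)
    return out


_PARAM_NAMES = ("intercept_single", "intercept_multiple", "slope_single", "slope_multiple")


def _fit(data: pd.DataFrame, spec: HierModelSpec) -> InteractionResult:
    linear = spec.outcome_kind == "linear"
    groups = _group_arrays(data, spec, binary_outcome=not linear)
    (x_s, y_s), (x_m, y_m) = groups["single"], groups["multiple"]

    sampler_cls = _LinearGibbs if linear else _LogisticMwG
    sampler = sampler_cls(x_s, y_s, x_m, y_m, spec)

    n_rec = 5 if linear else 4
    chains = np.empty((spec.chains, spec.draws, n_rec))
    for c in range(spec.chains):
        rng = np.random.default_rng((spec.seed, c))
        state = sampler.init_state(rng)
        for _ in range(spec.warmup):
            sampler.scan(state, rng)
        for i in range(spec.draws):
            sampler.scan(state, rng)
            chains[c, i] = sampler.record(state)

    rhats = {
        name: float(az.rhat(chains[:, :, j])) for j, name in enumerate(_PARAM_NAMES)
    }
    rhat_max = float(np.nanmax(list(rhats.values())))

    # flatten chain-major so single/multiple draws stay aligned
    flat = chains.reshape(-1, n_rec)
    draw_map = {name: flat[:, j] for j, name in enumerate(_PARAM_NAMES)}
    if linear:
        draw_map["sigma"] = flat[:, 4]

    diff_summary, substantial = difference_distribution(
        draw_map["slope_single"], draw_map["slope_multiple"], spec.hpdi_mass
    )
    diagnostics = {
        "rhat_max": rhat_max,
        "rhat": rhats,
        "converged": bool(rhat_max < spec.rhat_threshold),
        "n_draws": int(flat.shape[0]),
        "chains": spec.chains,
        "seed": spec.seed,
    }
    if not linear:
        with np.errstate(invalid="ignore"):
            diagnostics["mh_acceptance"] = list(sampler.accepts / np.maximum(sampler.attempts, 1))
    return InteractionResult(
        slope_single=summarize_posterior(draw_map["slope_single"], spec.hpdi_mass),
        slope_multiple=summarize_posterior(draw_map["slope_multiple"], spec.hpdi_mass),
        difference=diff_summary,
        substantial=substantial,
        intercept_single=summarize_posterior(draw_map["intercept_single"], spec.hpdi_mass),
        intercept_multiple=summarize_posterior(draw_map["intercept_multiple"], spec.hpdi_mass),
        n_single=len(y_s),
        n_multiple=len(y_m),
        diagnostics=diagnostics,
        draws=draw_map,
    )


def fit_hier_linear(data: pd.DataFrame, spec: HierModelSpec | None = None) -> InteractionResult:
    """Hierarchical linear regression of the outcome on log lesion volume.

    ``data`` needs the outcome column (default ``nihss``), the raw volume
    column (default ``dwi_vol_ml``; natural log taken internally) and the
    boolean group column (default ``mal``). Rows with missing values in
    any of the three are dropped (complete-case).
    """
    spec = spec or HierModelSpec(outcome_kind="linear")
    if spec.outcome_kind != "linear":
        raise ValidationError("fit_hier_linear requires outcome_kind='linear'")
    return _fit(data, spec)


def fit_hier_logistic(data: pd.DataFrame, spec: HierModelSpec | None = None) -> InteractionResult:
    """Hierarchical logistic regression for a 0/1 outcome (e.g. mRS > 2)."""
    spec = spec or HierModelSpec(outcome_kind="logistic", outcome="mrs_gt2")
    if spec.outcome_kind != "logistic":
        raise ValidationError("fit_hier_logistic requires outcome_kind='logistic'")
    return _fit(data, spec)
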