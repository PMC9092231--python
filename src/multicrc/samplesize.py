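"""Simulation-based precision calculation for CRC study design.

Before fielding a capture-recapture study, one wants to know how precise the
eventual population size estimate will be for a planned set of per-event
sample sizes.  This module simulates whole studies from a hypothesised
population and summarises, across replicates, how often the estimate lands
within given tolerances of the truth.

Individual heterogeneity is a shared logit-scale random effect: individual i
is captured at event j with probability ``expit(mu_j + eps_i)`` where
``eps_i ~ Normal(0, sigma_h**2)``.  The amount of heterogeneity is elicited
as an odds ratio at a quantile — "q of the population has capture odds less
than r times the average individual" — giving ``sigma_h = ln(r) / Phi^{-1}(q)``.
The per-event intercepts ``mu_j`` are calibrated so the *expected* per-event
sample size matches the planned one.  Homogeneous designs are estimated with
the Mt log-linear model, heterogeneous ones with the Mth-normal model (the
same logit-normal family the generator draws from).

This doubles as the package's synthetic-data generator for the estimation
modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .loglinear import FitError, ModelSpec, fit_model
from .tables import CaptureHistoryTable, IndividualRecords, ValidationError, aggregate_individuals

__all__ = [
    "HeterogeneitySpec",
    "SimConfig",
    "PrecisionTable",
    "sigma_from_odds_quantile",
    "calibrate_event_intercepts",
    "simulate_study",
    "precision_simulation",
    "DEFAULT_TOLERANCES",
]

DEFAULT_TOLERANCES = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0)  # percent
DEFAULT_QUANTILES = (0.50, 0.80, 0.90, 0.95)


def sigma_from_odds_quantile(r: float, q: float = 0.90) -> float:
    """Logit-scale heterogeneity SD from an odds ratio r at quantile q.

    sigma_h = ln(r) / Phi^{-1}(q); r = 1 is the homogeneous population.
    """
    if r < 1:
        raise ValidationError("heterogeneity odds ratio must be >= 1")
    if not 0.5 < q < 1:
        raise ValidationError("quantile must lie in (0.5, 1)")
    return math.log(r) / float(stats.norm.ppf(q))


@dataclass(frozen=True)
class HeterogeneitySpec:
    odds_ratio: float = 1.0
    quantile: float = 0.90

    @property
    def sigma(self) -> float:
        return sigma_from_odds_quantile(self.odds_ratio, self.quantile)

    @property
    def homogeneous(self) -> bool:
        return self.odds_ratio == 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study-design scenario: true size, planned samples, heterogeneity."""

    N: int
    sample_sizes: tuple[float, ...]
    heterogeneity: HeterogeneitySpec = HeterogeneitySpec()
    replicates: int = 1000
    seed: int | None = None
    estimator: str | None = None  # None -> Mt iff homogeneous else Mth-normal

    def __post_init__(self):
        if any(not 0 < s < self.N for s in self.sample_sizes):
            raise ValidationError("each planned sample size must lie in (0, N)")
        if self.replicates < 1:
            raise ValidationError("need at least one replicate")
        if self.estimator not in (None, "Mt", "Mth-normal"):
            raise ValidationError("estimator must be 'Mt' or 'Mth-normal'")

    @property
    def k(self) -> int:
        return len(self.sample_sizes)

    def resolved_estimator(self) -> str:
        if self.estimator is not None:
            return self.estimator
        return "Mt" if self.heterogeneity.homogeneous else "Mth-normal"


def _expected_capture(mu: float, sigma: float, nodes) -> float:
    x, w = nodes
    return float(w @ special.expit(mu + sigma * x))


def _gh(n_nodes: int = 40):
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


def calibrate_event_intercepts(N: int, sample_sizes, sigma: float) -> np.ndarray:
    """Logit intercepts mu_j with E[expit(mu_j + eps)] = n_j / N.

    Solved by Gauss–Hermite quadrature plus root finding; for sigma = 0 this
    is just the logit of the target capture fraction.
    """
    targets = np.asarray(sample_sizes, dtype=float) / N
    if np.any((targets <= 0) | (targets >= 1)):
        raise ValidationError("target capture fractions must be in (0, 1)")
    if sigma == 0:
        return special.logit(targets)
    nodes = _gh()
    mus = []
    for frac in targets:
        try:
            mus.append(optimize.brentq(
                lambda m: _expected_capture(m, sigma, nodes) - frac, -30, 30,
                xtol=1e-12))
        except ValueError as exc:
            raise ValidationError(
                f"no intercept in (-30, 30) achieves capture fraction {frac}"
            ) from exc
    return np.array(mus)


def simulate_study(config: SimConfig, seed=None) -> CaptureHistoryTable:
    """Simulate one CRC study and aggregate the observed individuals.

    ``seed`` may be an int or an ``np.random.Generator``; per-event totals
    are binomial around the planned sizes (capture is Bernoulli, so planned
    sizes are expectations, not quotas).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed)
    sigma = config.heterogeneity.sigma
    mu = calibrate_event_intercepts(config.N, config.sample_sizes, sigma)
    for _ in range(100):
        eps = rng.normal(0.0, sigma, config.N) if sigma > 0 else 0.0
        p = special.expit(mu[None, :] + np.atleast_1d(eps)[:, None])
        caught = rng.random((config.N, config.k)) < p
        observed = caught[caught.any(axis=1)]
        if observed.shape[0] > 0:
            return aggregate_individuals(
                IndividualRecords(k=config.k, rows=observed.astype(np.int64)))
    raise ValidationError(
        "no individuals observed in 100 attempts; capture probabilities are "
        "too small for this design")


@dataclass(frozen=True)
class PrecisionTable:
    """Within-tolerance rates and relative-error quantiles over replicates."""

    tolerances: tuple[float, ...]            # percent
    within: tuple[float, ...]                # fraction of replicates within
    error_quantiles: dict[float, float]      # level -> |rel err| percent
    estimates: np.ndarray
    N: int
    estimator: str
    replicates: int
    failed: int

    def as_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "true_N": self.N,
            "replicates": self.replicates,
            "failed_fits": self.failed,
            "within_tolerance": {
                f"{t:g}%": w for t, w in zip(self.tolerances, self.within)
            },
            "abs_relative_error_quantiles": {
                f"{int(100 * q)}%": v for q, v in self.error_quantiles.items()
            },
            "estimate_mean": float(np.mean(self.estimates)),
            "estimate_median": float(np.median(self.estimates)),
        }


def precision_simulation(config: SimConfig,
                         tolerances=DEFAULT_TOLERANCES,
                         quantiles=DEFAULT_QUANTILES) -> PrecisionTable:
    """Replicate the study, estimate each time, and tabulate precision."""
    rng = np.random.default_rng(config.seed)
    est = config.resolved_estimator()
    spec = ModelSpec("Mt") if est == "Mt" else ModelSpec("Mth", "normal")
    estimates = []
    failed = 0
    for _ in range(config.replicates):
        table = simulate_study(config, seed=rng)
        try:
            estimates.append(fit_model(table, spec).N_hat)
        except (FitError, ValidationError):
            failed += 1
    if failed > 0.2 * config.replicates:
        raise ValidationError(
            f"{failed}/{config.replicates} fits failed; the planned samples "
            "are too small for stable estimation — increase them")
    estimates = np.asarray(estimates)
    rel = np.abs(estimates - config.N) / config.N * 100.0
    return PrecisionTable(
        tolerances=tuple(tolerances),
        within=tuple(float(np.mean(rel <= t)) for t in tolerances),
        error_quantiles={float(q): float(np.quantile(rel, q)) for q in quantiles},
        estimates=estimates,
        N=config.N,
        estimator=est,
        replicates=config.replicates,
        failed=failed,
    )
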