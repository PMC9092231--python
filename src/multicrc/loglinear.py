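"""Closed-population log-linear (Poisson regression) abundance estimation.

The expected counts of the ``2**k - 1`` observable capture histories are
modelled on the log scale as linear combinations of capture effects:

* ``M0`` — every event and every individual shares one capture probability;
* ``Mt`` — capture probability varies by event;
* ``Mh`` — capture probability varies across individuals;
* ``Mth`` — both.

Heterogeneous classes (Mh/Mth) need a functional form for the individual
log-odds distribution.  The column-based variants add a column g(c) of the
number of captures c to the design matrix: ``poisson2`` uses 2**c - 1,
``darroch`` c**2/2, ``gamma3.5`` -log(c + 3.5) + log(3.5).  The ``chao``
variant saturates the c >= 3 cells and yields a lower bound rather than an
estimate.  The ``normal`` variant is not column-based: it integrates a
Gaussian mixing distribution over the individual logit of capture by
Gauss–Hermite quadrature and maximises the conditional likelihood.

The never-captured cell is extrapolated as exp(beta0), so the abundance
estimate is ``N_hat = n + exp(beta0)`` with a delta-method standard error and
a Wald interval built on the log(N_hat - n) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import optimize, special, stats
import statsmodels.api as sm

from .tables import CaptureHistoryTable, ValidationError, observable_patterns

__all__ = [
    "ModelSpec",
    "LogLinearFit",
    "PairwiseRow",
    "ComparisonRow",
    "FitError",
    "EstimateUnboundedError",
    "build_design_matrix",
    "fit_model",
    "chao_lower_bound",
    "model_comparison",
    "pairwise_analysis",
    "profile_ci",
    "HETEROGENEITY_VARIANTS",
]

# configurable constants of the heterogeneity columns
POISSON_BASE = 2.0
GAMMA_SHIFT = 3.5

HETEROGENEITY_VARIANTS = ("normal", "poisson2", "darroch", "gamma3.5", "chao")


class FitError(RuntimeError):
    """A log-linear fit failed (nonconvergence or degenerate structure)."""


class EstimateUnboundedError(FitError):
    """No recaptures: the zero-cell extrapolation exp(beta0) is unbounded."""


@dataclass(frozen=True)
class ModelSpec:
    """A closed-population model class plus heterogeneity variant."""

    model_class: str
    variant: str = "none"

    def __post_init__(self):
        if self.model_class not in ("M0", "Mt", "Mh", "Mth"):
            raise ValidationError(f"unknown model class {self.model_class!r}")
        if self.model_class in ("M0", "Mt"):
            if self.variant != "none":
                raise ValidationError(
                    f"{self.model_class} takes no heterogeneity variant"
                )
        elif self.variant not in HETEROGENEITY_VARIANTS:
            raise ValidationError(
                f"{self.model_class} requires a variant from {HETEROGENEITY_VARIANTS}"
            )

    @property
    def label(self) -> str:
        if self.variant == "none":
            return self.model_class
        pretty = {"poisson2": "Poisson2", "darroch": "Darroch",
                  "gamma3.5": "Gamma3.5", "normal": "Normal", "chao": "Chao"}
        return f"{self.model_class} {pretty[self.variant]}"


@dataclass(frozen=True)
class LogLinearFit:
    spec: ModelSpec
    coefficients: dict[str, float]
    N_hat: float
    se: float
    ci: tuple[float, float]
    ci_level: float
    aic: float
    bic: float
    loglik: float
    fitted: np.ndarray
    n: int
    converged: bool = True
    is_lower_bound: bool = False
    n_params: int = 0
    warnings: tuple[str, ...] = ()


class Design(NamedTuple):
    X: np.ndarray
    names: tuple[str, ...]
    offset: np.ndarray


def _g(variant: str, c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if variant == "poisson2":
        return POISSON_BASE ** c - 1.0
    if variant == "darroch":
        return c ** 2 / 2.0
    if variant == "gamma3.5":
        return -np.log(c + GAMMA_SHIFT) + math.log(GAMMA_SHIFT)
    raise ValidationError(f"no heterogeneity column for variant {variant!r}")


def build_design_matrix(spec: ModelSpec, k: int) -> Design:
    """Design over the observable histories (canonical pattern order).

    All columns vanish at the hypothetical zero-capture history, so the
    intercept alone extrapolates the unobserved cell.  The ``chao`` variant
    carries a fixed offset log(k/(k-1)) on the doubleton cells, which makes
    the Mh-chao extrapolation coincide with Chao's moment lower bound.
    """
    if k < 2:
        raise ValidationError("need k >= 2 events")
    pats = np.array(observable_patterns(k))
    c = pats.sum(axis=1)
    cols: list[np.ndarray] = [np.ones(len(pats))]
    names: list[str] = ["intercept"]
    offset = np.zeros(len(pats))

    if spec.model_class in ("M0", "Mh"):
        cols.append(c.astype(float))
        names.append("captures")
    else:  # Mt, Mth
        for j in range(k):
            cols.append(pats[:, j].astype(float))
            names.append(f"event{j+1}")

    if spec.model_class in ("Mh", "Mth"):
        if spec.variant == "chao":
            for j in range(3, k + 1):
                cols.append((c == j).astype(float))
                names.append(f"c=={j}")
            offset = np.where(c == 2, math.log(k / (k - 1)), 0.0)
        elif spec.variant != "normal":
            cols.append(_g(spec.variant, c))
            names.append(spec.variant)
        else:
            raise ValidationError(
                "the normal variant is fit by mixture likelihood, not a design column"
            )
    return Design(np.column_stack(cols), tuple(names), offset)


def _wald_interval(N_hat: float, se: float, n: int, level: float) -> tuple[float, float]:
    """Wald interval on the log(N_hat - n) scale, so the bound stays above n."""
    z = stats.norm.ppf(0.5 + level / 2)
    excess = max(N_hat - n, 1e-12)
    if se <= 0 or not np.isfinite(se):
        return (N_hat, N_hat)
    se_log = se / excess
    return (n + excess * math.exp(-z * se_log), n + excess * math.exp(z * se_log))


def _fit_glm(t: CaptureHistoryTable, spec: ModelSpec, ci_level: float) -> LogLinearFit:
    design = build_design_matrix(spec, t.k)
    if int(t.counts[np.array(t.patterns).sum(axis=1) >= 2].sum()) == 0:
        raise EstimateUnboundedError(
            "estimate unbounded (no recaptures): every observed individual was "
            "captured exactly once"
        )
    model = sm.GLM(t.counts.astype(float), design.X,
                   family=sm.families.Poisson(), offset=design.offset)
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            # saturated designs trip benign perfect-prediction warnings
            _warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # perfect separation and friends
        raise FitError(f"{spec.label}: Poisson IRLS failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"{spec.label}: nonconvergent coefficients {res.params}")
    beta0 = float(res.params[0])
    var_beta0 = float(res.cov_params()[0, 0])
    if beta0 > 30 or not np.isfinite(var_beta0):
        raise EstimateUnboundedError(
            f"{spec.label}: intercept diverged; zero-cell extrapolation unbounded"
        )
    n = t.n
    N_hat = n + math.exp(beta0)
    var_N = math.exp(beta0) + math.exp(2 * beta0) * var_beta0
    se = math.sqrt(var_N)
    ll = float(res.llf)
    p = design.X.shape[1]
    return LogLinearFit(
        spec=spec,
        coefficients=dict(zip(design.names, map(float, res.params))),
        N_hat=N_hat,
        se=se,
        ci=_wald_interval(N_hat, se, n, ci_level),
        ci_level=ci_level,
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + math.log(n) * p,
        loglik=ll,
        fitted=np.asarray(res.mu, dtype=float),
        n=n,
        converged=bool(getattr(res, "converged", True)),
        is_lower_bound=(spec.variant == "chao"),
        n_params=p,
    )


# ---------------------------------------------------------------------------
# Normal (logit-normal mixing) variant, by conditional maximum likelihood


def _gh_nodes(n_nodes: int = 20) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


def _history_probs(mu: np.ndarray, sigma: float, pats: np.ndarray,
                   nodes: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, float]:
    """(P_h for observable histories, P_0) under logit-normal mixing."""
    x, w = nodes
    eta = mu[None, :] + sigma * x[:, None]          # nodes x events
    p = np.clip(special.expit(eta), 1e-14, 1 - 1e-14)
    logp, log1m = np.log(p), np.log1p(-p)
    # nodes x histories
    loglik = logp @ pats.T + log1m @ (1 - pats).T
    P_h = w @ np.exp(loglik)
    P_0 = float(w @ np.exp(log1m.sum(axis=1)))
    return P_h, P_0


def _fit_normal(t: CaptureHistoryTable, spec: ModelSpec, ci_level: float,
                n_nodes: int = 20) -> LogLinearFit:
    pats = np.array(t.patterns, dtype=float)
    counts = t.counts.astype(float)
    n = t.n
    k = t.k
    if n == 0:
        raise FitError("empty table")
    if int(t.counts[pats.sum(axis=1) >= 2].sum()) == 0:
        raise EstimateUnboundedError(
            "estimate unbounded (no recaptures): every observed individual was "
            "captured exactly once"
        )
    nodes = _gh_nodes(n_nodes)

    def nll(theta: np.ndarray) -> float:
        mu, sigma = theta[:k], math.exp(theta[k])
        P_h, P_0 = _history_probs(mu, sigma, pats, nodes)
        if P_0 >= 1.0 or np.any(P_h <= 0):
            return 1e12
        return -float(counts @ (np.log(P_h) - math.log1p(-P_0)))

    n_j = pats.T @ counts
    mu0 = special.logit(np.clip(n_j / (2.0 * n), 1e-4, 1 - 1e-4))
    best = None
    for log_sig in (math.log(0.05), math.log(0.4), math.log(1.2)):
        res = optimize.minimize(
            nll, np.append(mu0, log_sig), method="L-BFGS-B",
            bounds=[(-20, 10)] * k + [(math.log(1e-4), math.log(4.0))],
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("Mth-normal conditional likelihood failed to converge")
    mu_hat, sigma_hat = best.x[:k], math.exp(best.x[k])
    P_h, P_0 = _history_probs(mu_hat, sigma_hat, pats, nodes)
    N_hat = n / (1.0 - P_0)

    # curvature of the Poissonised likelihood l(logN, mu, log sigma)
    def poisson_ll(psi: np.ndarray) -> float:
        N = math.exp(psi[0])
        mu, sigma = psi[1:k + 1], math.exp(psi[k + 1])
        Ph, _ = _history_probs(mu, sigma, pats, nodes)
        if np.any(Ph <= 0):
            return -1e12
        return float(counts @ np.log(N * Ph)) - N

    psi_hat = np.concatenate([[math.log(N_hat)], mu_hat, [math.log(sigma_hat)]])
    var_logN = _hessian_var(poisson_ll, psi_hat)
    se = N_hat * math.sqrt(var_logN) if np.isfinite(var_logN) else float("nan")

    fitted = N_hat * P_h
    ll = float(np.sum(counts * np.log(fitted) - fitted - special.gammaln(counts + 1)))
    p = k + 2  # event intercepts, mixing SD, abundance
    warnings = ()
    if sigma_hat < 2e-4:
        warnings = ("mixing SD collapsed to the homogeneous boundary",)
    return LogLinearFit(
        spec=spec,
        coefficients={**{f"mu{j+1}": float(m) for j, m in enumerate(mu_hat)},
                      "sigma": float(sigma_hat)},
        N_hat=N_hat,
        se=se,
        ci=_wald_interval(N_hat, se, n, ci_level),
        ci_level=ci_level,
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + math.log(n) * p,
        loglik=ll,
        fitted=fitted,
        n=n,
        converged=bool(best.success),
        n_params=p,
        warnings=warnings,
    )


def _hessian_var(loglik: Callable[[np.ndarray], float], x: np.ndarray,
                 h: float = 1e-4) -> float:
    """First diagonal entry of the inverse observed information, numerically."""
    d = len(x)
    H = np.zeros((d, d))
    f0 = loglik(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            if i == j:
                H[i, i] = (loglik(x + ei) - 2 * f0 + loglik(x - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    loglik(x + ei + ej) - loglik(x + ei - ej)
                    - loglik(x - ei + ej) + loglik(x - ei - ej)
                ) / (4 * h ** 2)
    try:
        cov = np.linalg.inv(-H)
        v = float(cov[0, 0])
        return v if v > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


def fit_model(t: CaptureHistoryTable, spec: ModelSpec,
              ci_level: float = 0.95) -> LogLinearFit:
    """Fit one log-linear model and return abundance with uncertainty."""
    if t.n == 0:
        raise ValidationError("cannot fit a model to an empty table")
    if spec.variant == "normal":
        return _fit_normal(t, spec, ci_level)
    return _fit_glm(t, spec, ci_level)


def profile_ci(t: CaptureHistoryTable, spec: ModelSpec,
               level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood interval for N (column-based variants only).

    The unobserved cell is included with pseudo-count N - n (intercept-only
    design row, since every covariate vanishes there); the profile deviance
    over N is compared against the chi-square(1) cutoff.  More expensive but
    better calibrated than the Wald interval when counts are small.
    """
    if spec.variant == "normal":
        raise ValidationError("profile CI is available for column-based models")
    design = build_design_matrix(spec, t.k)
    X_full = np.vstack([np.eye(1, design.X.shape[1]).ravel(), design.X])
    offset_full = np.concatenate([[0.0], design.offset])
    n = t.n

    def max_ll(N: float) -> float:
        y = np.concatenate([[N - n], t.counts.astype(float)])
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.GLM(y, X_full, family=sm.families.Poisson(),
                         offset=offset_full).fit(maxiter=100, tol=1e-10)
        return float(res.llf)

    fit = fit_model(t, spec)
    N_hat = fit.N_hat
    ll_hat = max_ll(N_hat)
    cut = ll_hat - stats.chi2.ppf(level, 1) / 2

    def below(N: float) -> float:
        return max_ll(N) - cut

    lo_bracket = n + 1e-6
    lo = (optimize.brentq(below, lo_bracket, N_hat, xtol=1e-3)
          if below(lo_bracket) < 0 else lo_bracket)
    hi_end = N_hat
    step = max(N_hat - n, 1.0)
    while below(hi_end + step) > 0 and step < 1e9:
        hi_end += step
        step *= 2
    hi = optimize.brentq(below, hi_end, hi_end + step, xtol=1e-3)
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Chao moment lower bound


def chao_lower_bound(t: CaptureHistoryTable, ci_level: float = 0.95) -> LogLinearFit:
    """Chao's singleton/doubleton moment lower bound on abundance.

    ``N = n + f1**2 / (2 f2)`` with the bias-corrected form
    ``n + f1 (f1 - 1) / (2 (f2 + 1))`` when no doubletons were observed.
    The variance is Chao's (1987) asymptotic formula.
    """
    from .tables import descriptive_stats

    d = descriptive_stats(t)
    f1, f2 = d.f_i[0], d.f_i[1]
    n = t.n
    warnings: tuple[str, ...] = ()
    if f1 == 0:
        N_hat, var = float(n), 0.0
        warnings = ("no singletons: every individual recaptured; bound equals n",)
    elif f2 > 0:
        r = f1 / f2
        N_hat = n + f1 ** 2 / (2 * f2)
        var = f2 * (0.25 * r ** 4 + r ** 3 + 0.5 * r ** 2)
    else:
        N_hat = n + f1 * (f1 - 1) / 2.0
        var = (f1 * (f1 - 1) / 2.0
               + f1 * (2 * f1 - 1) ** 2 / 4.0
               - f1 ** 4 / (4.0 * N_hat))
        warnings = ("no doubletons: bias-corrected Chao bound used",)
    se = math.sqrt(max(var, 0.0))
    spec = ModelSpec("Mh", "chao")
    return LogLinearFit(
        spec=spec,
        coefficients={"f1": float(f1), "f2": float(f2)},
        N_hat=float(N_hat),
        se=se,
        ci=_wald_interval(N_hat, se, n, ci_level),
        ci_level=ci_level,
        aic=float("nan"),
        bic=float("nan"),
        loglik=float("nan"),
        fitted=t.counts.astype(float),
        n=n,
        is_lower_bound=True,
        n_params=2,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Model comparison and pairwise diagnostics


@dataclass(frozen=True)
class ComparisonRow:
    spec: ModelSpec
    fit: LogLinearFit | None
    error: str | None = None


def applicable_specs(k: int) -> list[ModelSpec]:
    """M0 and Mt always; heterogeneous classes only for k >= 3.

    With two events the heterogeneity columns are collinear with the capture
    count, so Mh/Mth are not identifiable and are excluded outright.
    """
    specs = [ModelSpec("M0"), ModelSpec("Mt")]
    if k >= 3:
        for cls in ("Mh", "Mth"):
            for variant in HETEROGENEITY_VARIANTS:
                specs.append(ModelSpec(cls, variant))
    return specs


def model_comparison(t: CaptureHistoryTable, ci_level: float = 0.95) -> list[ComparisonRow]:
    """Fit every applicable model; failures become flagged rows, never aborts.

    Rows are sorted by AIC (ties: BIC, then fewer parameters); failed fits
    sort last.
    """
    rows = []
    for spec in applicable_specs(t.k):
        try:
            rows.append(ComparisonRow(spec, fit_model(t, spec, ci_level)))
        except (FitError, ValidationError) as exc:
            rows.append(ComparisonRow(spec, None, str(exc)))

    def key(row: ComparisonRow):
        if row.fit is None or not np.isfinite(row.fit.aic):
            return (1, float("inf"), float("inf"), float("inf"))
        return (0, row.fit.aic, row.fit.bic, row.fit.n_params)

    return sorted(rows, key=key)


@dataclass(frozen=True)
class PairwiseRow:
    events: tuple[int, int]  # 1-based
    n_a: int
    n_b: int
    m: int
    N_hat: float
    se: float
    ci: tuple[float, float]
    flag: str = ""

    @property
    def label(self) -> str:
        return f"pa{self.events[0]}{self.events[1]}"


def pairwise_analysis(t: CaptureHistoryTable, ci_level: float = 0.95) -> list[PairwiseRow]:
    """Chapman two-list estimates for every pair of events.

    Similar estimates across pairs are consistent with list independence;
    divergent pairs point at dependence between those events.  The Chapman
    estimator ``(n_a+1)(n_b+1)/(m+1) - 1`` with Seber's variance is used;
    intervals are truncated below at the number of distinct individuals seen
    by the pair.
    """
    z = stats.norm.ppf(0.5 + ci_level / 2)
    rows = []
    for a, b in combinations(range(t.k), 2):
        n_a, n_b, m = t.marginal_pair(a, b)
        N_hat = (n_a + 1) * (n_b + 1) / (m + 1) - 1
        var = ((n_a + 1) * (n_b + 1) * (n_a - m) * (n_b - m)
               / ((m + 1) ** 2 * (m + 2)))
        se = math.sqrt(var)
        floor = n_a + n_b - m
        ci = (max(N_hat - z * se, floor), max(N_hat + z * se, floor))
        rows.append(PairwiseRow(
            events=(a + 1, b + 1), n_a=n_a, n_b=n_b, m=m,
            N_hat=N_hat, se=se, ci=ci,
            flag="no overlap: lower bound only" if m == 0 else "",
        ))
    return rows
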