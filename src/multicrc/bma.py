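"""Bayesian model averaging over decomposable models of list dependence.

Encounter events may not be independent draws from the population (the same
neighbourhoods may be canvassed twice, say).  Each pattern of pairwise list
dependence is represented as a graph on the k events; restricting attention
to *decomposable* (chordal) graphs gives every model a closed-form marginal
likelihood under a hyper-Dirichlet prior on the 2**k contingency table that
factorises over the graph's cliques and separators.  Averaging the posterior
over all decomposable models — weighted by how well each explains the
observed overlap — yields a population-size posterior that carries model
uncertainty, instead of betting on a single dependence structure.

The per-cell prior weight ``delta`` (default ``2**-k``) acts as the
complexity control: smaller values put less prior weight on models with
rich interactions.  The population-size prior is either the scale-invariant
``1/N`` improper prior or a truncated log-normal elicited from a believed
median and 90th percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .tables import CaptureHistoryTable, ValidationError

__all__ = [
    "PriorSpec",
    "DecomposableModel",
    "BMAConfig",
    "BMAPosterior",
    "Z90",
    "is_chordal",
    "enumerate_decomposable_models",
    "elicit_lognormal_prior",
    "log_marginal_likelihood",
    "posterior_over_N",
]

Z90 = float(norm.ppf(0.90))  # ~1.281552


@dataclass(frozen=True)
class PriorSpec:
    """Prior on the population size N, truncated to {n, ..., N_max}."""

    kind: str  # "noninformative" or "lognormal"
    N_max: int | None = None
    median: float | None = None
    q90: float | None = None
    mu: float | None = None
    sigma: float | None = None

    def log_density(self, N: np.ndarray) -> np.ndarray:
        """Unnormalised log prior mass at integer sizes N."""
        N = np.asarray(N, dtype=float)
        if self.kind == "noninformative":
            return -np.log(N)
        return (-np.log(N) - np.log(self.sigma)
                - 0.5 * ((np.log(N) - self.mu) / self.sigma) ** 2)


def elicit_lognormal_prior(median: float, q90: float, N_max: int) -> PriorSpec:
    """Turn a believed median and 90th percentile into a log-normal prior.

    mu = ln(median); sigma = (ln q90 - ln median) / z_0.90.
    """
    if median <= 0:
        raise ValidationError("prior median must be positive")
    if q90 <= median:
        raise ValidationError("90th percentile must exceed median")
    if N_max < q90:
        raise ValidationError("truncation bound N_max must be at least q90")
    return PriorSpec(
        kind="lognormal", N_max=int(N_max), median=median, q90=q90,
        mu=math.log(median), sigma=(math.log(q90) - math.log(median)) / Z90,
    )


@dataclass(frozen=True)
class BMAConfig:
    delta: float | None = None  # default 2**-k, resolved against the table
    grid_step: int | None = None
    level: float = 0.95
    model_log_prior: Callable[["DecomposableModel"], float] | None = None

    def resolve_delta(self, k: int) -> float:
        d = 2.0 ** -k if self.delta is None else self.delta
        if d <= 0:
            raise ValidationError("delta must be positive")
        return d


# ---------------------------------------------------------------------------
# Chordal graphs: maximum cardinality search, cliques, separators


def _mcs_order(k: int, adj: list[set[int]]) -> list[int]:
    """Maximum cardinality search visit order (a PEO reversed iff chordal)."""
    weights = [0] * k
    visited = [False] * k
    order = []
    for _ in range(k):
        v = max((u for u in range(k) if not visited[u]), key=lambda u: (weights[u], -u))
        visited[v] = True
        order.append(v)
        for w in adj[v]:
            if not visited[w]:
                weights[w] += 1
    return order


def _chordal_decomposition(k: int, edges: frozenset) -> tuple[bool, list, list]:
    """(is_chordal, maximal cliques, separators with multiplicity).

    Runs maximum cardinality search; the graph is chordal iff every vertex's
    earlier neighbours form a clique along the MCS order.  Cliques are read
    off the MCS order and separators from the running intersection of the
    resulting perfect clique sequence (empty separators join components).
    """
    adj: list[set[int]] = [set() for _ in range(k)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    order = _mcs_order(k, adj)
    pos = {v: i for i, v in enumerate(order)}
    candidate_cliques: list[frozenset[int]] = []
    for i, v in enumerate(order):
        earlier = {u for u in adj[v] if pos[u] < i}
        for a, b in combinations(earlier, 2):
            if b not in adj[a]:
                return False, [], []
        candidate_cliques.append(frozenset(earlier | {v}))
    # keep maximal cliques, in MCS order (a perfect sequence for chordal graphs)
    cliques = [c for c in candidate_cliques
               if not any(c < d for d in candidate_cliques)]
    seen_maximal: list[frozenset[int]] = []
    uniq = []
    for c in cliques:
        if c not in seen_maximal:
            seen_maximal.append(c)
            uniq.append(c)
    cliques = uniq
    separators = []
    running: set[int] = set()
    for i, c in enumerate(cliques):
        if i > 0:
            separators.append(frozenset(c & running))
        running |= c
    return True, cliques, separators


def is_chordal(k: int, edges) -> bool:
    return _chordal_decomposition(k, frozenset(edges))[0]


@dataclass(frozen=True)
class DecomposableModel:
    """A chordal dependence graph on the k events, with its decomposition."""

    k: int
    edges: frozenset
    cliques: tuple[frozenset, ...]
    separators: tuple[frozenset, ...]

    @property
    def label(self) -> str:
        if not self.edges:
            return "independence"
        return "+".join(
            f"[{''.join(str(v+1) for v in sorted(c))}]" for c in self.cliques
        )

    @classmethod
    def from_edges(cls, k: int, edges) -> "DecomposableModel":
        edges = frozenset(tuple(sorted(e)) for e in edges)
        ok, cliques, seps = _chordal_decomposition(k, edges)
        if not ok:
            raise ValidationError("graph is not chordal (no closed-form marginal)")
        return cls(k=k, edges=edges, cliques=tuple(cliques), separators=tuple(seps))


def enumerate_decomposable_models(k: int) -> list[DecomposableModel]:
    """All labelled decomposable dependence graphs on k events.

    8 models for k=3, 61 for k=4, 822 for k=5.  Beyond 5 lists the model
    space (and each model's table) grows explosively, so k is capped.
    """
    if not 3 <= k <= 5:
        raise ValidationError(
            "model averaging supports 3 to 5 encounter events "
            "(the model space explodes beyond 5)"
        )
    all_edges = list(combinations(range(k), 2))
    models = []
    for bits in product((0, 1), repeat=len(all_edges)):
        edges = frozenset(e for e, b in zip(all_edges, bits) if b)
        ok, cliques, seps = _chordal_decomposition(k, edges)
        if ok:
            models.append(DecomposableModel(
                k=k, edges=edges, cliques=tuple(cliques), separators=tuple(seps)))
    models.sort(key=lambda m: (len(m.edges), sorted(m.edges)))
    return models


# ---------------------------------------------------------------------------
# Hyper-Dirichlet marginal likelihood


def _marginal_cells(t: CaptureHistoryTable, subset: frozenset) -> tuple[np.ndarray, int]:
    """Observed counts over the 2**|A| cells of the marginal table on A.

    Returns (counts per marginal cell, index of the all-zero marginal cell);
    the unobserved individuals (N - n) belong to the all-zero cell.
    """
    members = sorted(subset)
    pats = np.array(t.patterns)
    size = 2 ** len(members)
    counts = np.zeros(size, dtype=np.int64)
    if members:
        idx = np.zeros(len(pats), dtype=int)
        for bit, j in enumerate(members):
            idx |= pats[:, j] << bit
    else:
        idx = np.zeros(len(pats), dtype=int)
    np.add.at(counts, idx, t.counts)
    return counts, 0


def _model_terms(model: DecomposableModel, t: CaptureHistoryTable, delta: float):
    """Constant and N-dependent pieces of the log marginal likelihood.

    For each clique/separator A the term is

        ln G(a_A) - ln G(a_A + N) + sum_cells [ln G(a_cell + n_cell) - ln G(a_cell)]

    with per-marginal-cell prior weight ``a_cell = delta * 2**(k - |A|)`` and
    ``a_A = delta * 2**k``.  Only the all-zero cell's count involves N (it
    absorbs the N - n never-captured individuals), and cliques minus
    separators leave exactly one ``-ln G(a_A + N)`` term.
    """
    k = t.k
    alpha_total = delta * 2 ** k
    const = 0.0
    zero_terms: list[tuple[float, int]] = []  # (alpha0, observed zero-cell count), sign
    signs: list[int] = []
    for subsets, sign in ((model.cliques, +1), (model.separators, -1)):
        for A in subsets:
            counts, zero_idx = _marginal_cells(t, A)
            alpha_cell = delta * 2 ** (k - len(A))
            const += sign * (gammaln(alpha_total))
            for i, c in enumerate(counts):
                if i == zero_idx:
                    zero_terms.append((alpha_cell, int(c)))
                    signs.append(sign)
                else:
                    const += sign * (gammaln(alpha_cell + c) - gammaln(alpha_cell))
            const -= sign * gammaln(alpha_cell)  # the zero cell's -ln G(a_cell)
    return const, zero_terms, signs, alpha_total


def _log_ml_grid(model: DecomposableModel, t: CaptureHistoryTable,
                 N: np.ndarray, delta: float) -> np.ndarray:
    """Vectorised log marginal likelihood over a grid of population sizes."""
    n = t.n
    N = np.asarray(N, dtype=float)
    if np.any(N < n):
        raise ValidationError("population size cannot be below the observed count")
    const, zero_terms, signs, alpha_total = _model_terms(model, t, delta)
    out = np.full(N.shape, const)
    # multinomial coefficient N! / ((N-n)! * prod x_h!)
    out += gammaln(N + 1) - gammaln(N - n + 1) - float(gammaln(t.counts + 1).sum())
    out -= gammaln(alpha_total + N)  # net count over cliques minus separators is 1
    for (alpha0, z), sign in zip(zero_terms, signs):
        out += sign * gammaln(alpha0 + z + (N - n))
    return out


def log_marginal_likelihood(model: DecomposableModel, t: CaptureHistoryTable,
                            N: int, delta: float | None = None) -> float:
    """Closed-form hyper-Dirichlet log marginal likelihood at one N."""
    delta = BMAConfig(delta=delta).resolve_delta(t.k)
    return float(_log_ml_grid(model, t, np.array([N]), delta)[0])


# ---------------------------------------------------------------------------
# Posterior over N


@dataclass(frozen=True)
class BMAPosterior:
    grid: np.ndarray
    mass: np.ndarray                      # posterior over N, sums to 1
    models: tuple[DecomposableModel, ...]
    model_probs: np.ndarray               # posterior model probabilities
    conditional: np.ndarray               # models x grid, rows sum to 1
    mean: float
    median: float
    ci: tuple[float, float]
    level: float
    delta: float
    prior: PriorSpec

    def summary(self) -> dict:
        top = int(np.argmax(self.model_probs))
        return {
            "mean": self.mean,
            "median": self.median,
            "ci": list(self.ci),
            "level": self.level,
            "top_model": self.models[top].label,
            "top_model_prob": float(self.model_probs[top]),
        }


def _grid(n: int, N_max: int, step: int | None) -> np.ndarray:
    if step is None:
        step = max(1, (N_max - n) // 50_000)
    return np.arange(n, N_max + 1, step, dtype=np.int64)


def posterior_over_N(t: CaptureHistoryTable, prior: PriorSpec | None = None,
                     config: BMAConfig | None = None) -> BMAPosterior:
    """Grid posterior over N averaged over all decomposable models.

    Per (model, N) the joint log weight is the hyper-Dirichlet marginal
    likelihood plus the log N prior plus the log model prior (uniform unless
    a hook is supplied); marginalising over models gives the N posterior and
    over N the model probabilities.
    """
    if t.n == 0:
        raise ValidationError("empty table: nothing observed to average over")
    config = config or BMAConfig()
    if prior is None:
        prior = PriorSpec(kind="noninformative", N_max=20 * t.n)
    N_max = prior.N_max if prior.N_max is not None else 20 * t.n
    if N_max <= t.n:
        raise ValidationError("N_max must exceed the number observed")
    delta = config.resolve_delta(t.k)
    grid = _grid(t.n, int(N_max), config.grid_step)
    models = enumerate_decomposable_models(t.k)
    log_prior_N = prior.log_density(grid)
    joint = np.empty((len(models), len(grid)))
    for i, m in enumerate(models):
        joint[i] = _log_ml_grid(m, t, grid, delta) + log_prior_N
        if config.model_log_prior is not None:
            joint[i] += config.model_log_prior(m)
    total = logsumexp(joint)
    log_mass_N = logsumexp(joint, axis=0) - total
    mass = np.exp(log_mass_N)
    model_probs = np.exp(logsumexp(joint, axis=1) - total)
    conditional = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    mean = float(mass @ grid)
    cdf = np.cumsum(mass)
    lo_q = (1 - config.level) / 2
    median = float(grid[np.searchsorted(cdf, 0.5)])
    ci = (float(grid[np.searchsorted(cdf, lo_q)]),
          float(grid[np.searchsorted(cdf, 1 - lo_q)]))
    return BMAPosterior(
        grid=grid, mass=mass, models=tuple(models), model_probs=model_probs,
        conditional=conditional, mean=mean, median=median, ci=ci,
        level=config.level, delta=delta, prior=prior,
    )
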