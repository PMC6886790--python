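"""Structural metrics of bipartite plant–pollinator networks.

Connectance here follows the field study this package models: the
proportion of realized links is written BC = 2L/(N_po * N_pl), which
carries a factor 2 relative to the convention L/(N_po * N_pl) used by most
network software.  Both are exposed; the doubled form is the default so
that reported values match the study's tables.

Nestedness is NODF (Almeida-Neto's nestedness based on overlap and
decreasing fill), scored 0–100, with significance from constrained network
randomizations that preserve the numbers of plants, pollinators and links.
Degree distributions are compared across exponential, power-law and
truncated power-law models by discrete maximum likelihood with AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .core import (
    DEFAULT_CALENDAR,
    BipartiteNetwork,
    FrequencyTable,
    SeasonCalendar,
    VisitRecord,
    build_network,
    interaction_frequency,
)

__all__ = [
    "bipartite_connectance",
    "DegreeSummary",
    "degree_summary",
    "nodf",
    "NestednessResult",
    "nestedness_significance",
    "DegreeFit",
    "fit_degree_models",
    "seasonal_metric_test",
    "METRIC_FUNCTIONS",
]


def bipartite_connectance(net: BipartiteNetwork, doubled: bool = True) -> float:
    """Connectance BC = 2L/(N_po*N_pl); set ``doubled=False`` for L/(N_po*N_pl)."""
    if net.n_plants == 0 or net.n_pollinators == 0:
        raise ValueError("connectance undefined: one side of the network is empty")
    factor = 2 if doubled else 1
    return factor * net.n_links / (net.n_pollinators * net.n_plants)


@dataclass(frozen=True)
class DegreeSummary:
    """Per-node degrees and weighted degrees with per-side summaries."""

    plant_degree: Mapping[str, int]
    pollinator_degree: Mapping[str, int]
    plant_weighted: Mapping[str, float] | None = None
    pollinator_weighted: Mapping[str, float] | None = None

    def _side(self, deg: Mapping[str, int]) -> dict:
        vals = list(deg.values())
        return {"mean": float(np.mean(vals)), "min": int(min(vals)), "max": int(max(vals))}

    @property
    def plant_stats(self) -> dict:
        return self._side(self.plant_degree)

    @property
    def pollinator_stats(self) -> dict:
        return self._side(self.pollinator_degree)

    @property
    def mean_plant_degree(self) -> float:
        return self.plant_stats["mean"]

    @property
    def mean_pollinator_degree(self) -> float:
        return self.pollinator_stats["mean"]


def degree_summary(net: BipartiteNetwork, freqs: FrequencyTable | None = None) -> DegreeSummary:
    """Species degrees (partner counts) and, given frequencies, weighted degrees."""
    if net.is_empty:
        raise ValueError("degree summary undefined on an empty network")
    pw = bw = None
    if freqs is not None:
        pw = freqs.plant_weighted_degree()
        bw = freqs.pollinator_weighted_degree()
    return DegreeSummary(
        plant_degree=net.plant_degree(),
        pollinator_degree=net.pollinator_degree(),
        plant_weighted=pw,
        pollinator_weighted=bw,
    )


def _as_matrix(net_or_matrix) -> np.ndarray:
    if isinstance(net_or_matrix, BipartiteNetwork):
        return net_or_matrix.incidence_frame().to_numpy()
    return (np.asarray(net_or_matrix) > 0).astype(int)


def nodf(net_or_matrix) -> float:
    """NODF nestedness of a binary incidence matrix, in [0, 100].

    A pair of rows (and, symmetrically, columns) contributes the percentage
    of the poorer row's links that fall inside the richer row's links, but
    only when the fills strictly decrease; equal fills contribute 0.  The
    score averages the contributions over all row pairs and column pairs.
    """
    A = _as_matrix(net_or_matrix)
    m, n = A.shape
    if m < 2 or n < 2:
        raise ValueError("NODF needs an incidence matrix with >= 2 rows and >= 2 columns")
    total = 0.0
    for M in (A, A.T):
        fills = M.sum(axis=1)
        overlap = M @ M.T
        r = fills[:, None]
        c = fills[None, :]
        # strict decreasing fill: richer row i, poorer row j with fill > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where((r > c) & (c > 0), overlap / np.where(c > 0, c, 1), 0.0)
        total += 100.0 * (np.sum(frac) )  # each unordered pair counted once via (r > c)
    n_pairs = m * (m - 1) / 2 + n * (n - 1) / 2
    return float(total / n_pairs)


@dataclass(frozen=True)
class NestednessResult:
    nodf: float
    n_rand: int
    p_value: float
    null_model: str
    seed: int | None
    null_values: np.ndarray = field(repr=False, default=None)


def _random_incidence(
    rng: np.random.Generator, n_rows: int, n_cols: int, n_links: int, weights: np.ndarray | None
) -> np.ndarray:
    cells = rng.choice(n_rows * n_cols, size=n_links, replace=False, p=weights)
    M = np.zeros(n_rows * n_cols, dtype=int)
    M[cells] = 1
    return M.reshape(n_rows, n_cols)


def nestedness_significance(
    net: BipartiteNetwork,
    n_rand: int = 999,
    null_model: str = "fixedL",
    seed: int | None = None,
) -> NestednessResult:
    """Empirical NODF significance against constrained random networks.

    ``fixedL`` (default) preserves the numbers of plants, pollinators and
    links, wiring L distinct links uniformly at random.  ``marginal``
    additionally weights cell inclusion by the product of the observed row
    and column marginals, preserving expected marginal proportions.
    The p-value is (1 + #{null NODF >= observed}) / (1 + n_rand).
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99 for a meaningful empirical p-value")
    A = _as_matrix(net)
    m, n = A.shape
    L = int(A.sum())
    if L > m * n:
        raise ValueError("cannot place more links than cells")
    if null_model == "fixedL":
        weights = None
    elif null_model == "marginal":
        w = np.outer(A.sum(axis=1), A.sum(axis=0)).astype(float).ravel()
        weights = w / w.sum()
    else:
        raise ValueError(f"unknown null model {null_model!r}; use 'fixedL' or 'marginal'")
    observed = nodf(A)
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_rand)
    for k in range(n_rand):
        null_vals[k] = nodf(_random_incidence(rng, m, n, L, weights))
    p = (1 + int(np.sum(null_vals >= observed))) / (1 + n_rand)
    return NestednessResult(
        nodf=observed, n_rand=n_rand, p_value=p, null_model=null_model, seed=seed,
        null_values=null_vals,
    )


# --- degree-distribution model selection -------------------------------------

@dataclass(frozen=True)
class DegreeFit:
    """One fitted degree-distribution model with its AIC rank."""

    model: str
    params: Mapping[str, float]
    log_likelihood: float
    aic: float
    n_params: int
    rank: int = 0


def _log_pmf_exponential(support: np.ndarray, rate: float) -> np.ndarray:
    logits = -rate * support
    return logits - logsumexp(logits)


def _log_pmf_powerlaw(support: np.ndarray, gamma: float) -> np.ndarray:
    logits = -gamma * np.log(support)
    return logits - logsumexp(logits)


def _log_pmf_truncated(support: np.ndarray, gamma: float, cutoff: float) -> np.ndarray:
    logits = -gamma * np.log(support) - support / cutoff
    return logits - logsumexp(logits)


def fit_degree_models(degrees: Sequence[int]) -> list[DegreeFit]:
    """Discrete ML fits of exponential / power-law / truncated power-law models.

    Fits are over the observed support k = 1..max(degrees) with numerically
    normalized probability mass functions; models are ranked by AIC
    (ties broken in favour of fewer parameters).  Requires >= 10
    observations with max degree >= 2 and non-degenerate dispersion.
    """
    k = np.asarray(list(degrees), dtype=int)
    if k.size < 10:
        raise ValueError(f"need >= 10 degree observations, got {k.size}")
    if np.any(k < 1):
        raise ValueError("degrees must be positive integers")
    if k.max() < 2:
        raise ValueError("max degree must be >= 2")
    if np.all(k == k[0]):
        raise ValueError("degenerate distribution: all degrees equal")
    support = np.arange(1, k.max() + 1)
    counts = np.bincount(k, minlength=k.max() + 1)[1:].astype(float)

    def nll(log_pmf: np.ndarray) -> float:
        return -float(np.dot(counts, log_pmf))

    fits: list[DegreeFit] = []

    res = minimize_scalar(
        lambda r: nll(_log_pmf_exponential(support, r)), bounds=(1e-9, 50.0), method="bounded"
    )
    ll = -res.fun
    fits.append(DegreeFit("exponential", {"rate": float(res.x)}, ll, 2 * 1 - 2 * ll, 1))

    res = minimize_scalar(
        lambda g: nll(_log_pmf_powerlaw(support, g)), bounds=(1e-9, 25.0), method="bounded"
    )
    ll = -res.fun
    fits.append(DegreeFit("power-law", {"gamma": float(res.x)}, ll, 2 * 1 - 2 * ll, 1))

    def tpl_obj(theta: np.ndarray) -> float:
        gamma, log_cutoff = theta
        return nll(_log_pmf_truncated(support, gamma, np.exp(log_cutoff)))

    best = None
    bounds = [(0.0, 25.0), (-6.0, 15.0)]
    for g0, lc0 in ((1.0, np.log(k.max() + 1.0)), (0.1, 1.0), (2.0, np.log(5.0))):
        res = minimize(tpl_obj, x0=np.array([g0, lc0]), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ll = -float(best.fun)
    fits.append(
        DegreeFit(
            "truncated power-law",
            {"gamma": float(best.x[0]), "cutoff": float(np.exp(best.x[1]))},
            ll,
            2 * 2 - 2 * ll,
            2,
        )
    )

    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].n_params))
    ranked = []
    for rank, i in enumerate(order, start=1):
        f = fits[i]
        ranked.append(DegreeFit(f.model, f.params, f.log_likelihood, f.aic, f.n_params, rank))
    return ranked


# --- seasonal difference test ------------------------------------------------

METRIC_FUNCTIONS: dict[str, Callable[[BipartiteNetwork], float]] = {
    "network_size": lambda net: float(net.n_plants + net.n_pollinators),
    "n_plants": lambda net: float(net.n_plants),
    "n_pollinators": lambda net: float(net.n_pollinators),
    "n_links": lambda net: float(net.n_links),
    "n_visits": lambda net: float(net.n_visits),
    "connectance": bipartite_connectance,
    "mean_plant_degree": lambda net: degree_summary(net).mean_plant_degree,
    "mean_pollinator_degree": lambda net: degree_summary(net).mean_pollinator_degree,
    "nodf": nodf,
}

_MAX_REDRAWS = 1000


def seasonal_metric_test(
    records: Sequence[VisitRecord],
    cal: SeasonCalendar = DEFAULT_CALENDAR,
    metric: str = "network_size",
    n_perm: int = 999,
    seed: int | None = None,
    seasons: tuple[str, str] = ("rainy", "dry"),
) -> dict:
    """One-tailed permutation test of a seasonal difference in a network metric.

    Records are randomly reassigned to the two seasons preserving each
    season's record count; the seasonal networks are rebuilt and the metric
    difference recomputed.  The tail follows the sign of the observed
    difference (first listed season minus second); permutations on which
    the metric is undefined are redrawn, with a cap.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if metric not in METRIC_FUNCTIONS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRIC_FUNCTIONS)}")
    fn = METRIC_FUNCTIONS[metric]
    season_a, season_b = seasons
    labels = [cal.season_of_month(r.date.month) for r in records]
    idx_a = [i for i, s in enumerate(labels) if s == season_a]
    idx_b = [i for i, s in enumerate(labels) if s == season_b]
    if not idx_a or not idx_b:
        raise ValueError("records must span both seasons")

    def metric_diff(group_a: Sequence[int], group_b: Sequence[int]) -> float:
        net_a = build_network([records[i] for i in group_a], period="all", cal=cal)
        net_b = build_network([records[i] for i in group_b], period="all", cal=cal)
        return fn(net_a) - fn(net_b)

    observed = metric_diff(idx_a, idx_b)
    rng = np.random.default_rng(seed)
    pool = np.array(idx_a + idx_b)
    n_a = len(idx_a)
    hits = 0
    redraws = 0
    done = 0
    while done < n_perm:
        perm = rng.permutation(pool)
        try:
            diff = metric_diff(perm[:n_a].tolist(), perm[n_a:].tolist())
        except ValueError:
            redraws += 1
            if redraws > _MAX_REDRAWS:
                raise RuntimeError(
                    "metric undefined on too many permuted seasonal splits"
                ) from None
            continue
        if (observed >= 0 and diff >= observed) or (observed < 0 and diff <= observed):
            hits += 1
        done += 1
    return {
        "metric": metric,
        "seasons": seasons,
        "observed_diff": observed,
        "n_perm": n_perm,
        "p_value": (1 + hits) / (1 + n_perm),
        "redraws": redraws,
        "seed": seed,
    }
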