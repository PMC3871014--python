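"""Monte-Carlo CSR testing, FDR q-values, and network Q-Q diagnostics.

The null hypothesis for every dendrite is complete spatial randomness (CSR):
spines form a homogeneous Poisson process along the network, i.e. locations
are i.i.d. uniform by arc length.  The test statistic is the maximum absolute
deviation (MAD) of the Ang-corrected empirical K-function from its CSR value
K(t) = t; its null distribution is obtained by re-simulating the same number
of spines uniformly on the same network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .kfunction import KFunctionEstimate, default_t_grid, empirical_k, mad_statistic
from .network import LinearNetwork, NetworkLocation, SpinePattern, make_spine

logger = logging.getLogger(__name__)


@dataclass
class CSRTestResult:
    dendrite_id: str
    observed_d: float
    draws: np.ndarray
    nsim: int
    p_value: float
    seed: int | None = None
    n: int = 0
    total_length: float = 0.0


@dataclass
class Envelope:
    t_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    nsim: int
    level: float
    k_paths: np.ndarray | None = None


@dataclass
class QValueResult:
    p_values: np.ndarray
    pi0: float
    q_values: np.ndarray
    method: str = "storey"


@dataclass
class QQDiagnostic:
    """Observed vs. CSR-theoretical quantiles of soma distance for one dendrite."""

    observed: np.ndarray
    theoretical: np.ndarray

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(dict(theoretical=self.theoretical, observed=self.observed))


# ------------------------------------------------------------------ simulation
def simulate_csr(
    net: LinearNetwork,
    n: int,
    rng: np.random.Generator,
    div: int = 7,
    experiment: int = 1,
    dendrite_id: str = "csr-sim",
) -> SpinePattern:
    """n spine locations i.i.d. uniform by arc length on the network.

    Uniform draws on [0, ℓ_T] are mapped to (segment, offset) through the
    cumulative segment lengths; types default to mushroom and can be
    reassigned downstream.
    """
    if n < 0:
        raise ValidationError("n must be non-negative")
    arcs = np.sort(rng.uniform(0.0, net.total_length, size=n))
    spines = [
        make_spine(net, net.location_at_arc(a), "mushroom", div=div, experiment=experiment)
        for a in arcs
    ]
    return SpinePattern(network=net, spines=spines, dendrite_id=dendrite_id)


def mc_pvalue(observed_d: float, draws: np.ndarray) -> float:
    """Conservative Monte-Carlo p-value (1 + #{d_i ≥ d_obs}) / (nsim + 1)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValidationError("draws must be non-empty")
    return float((1 + np.sum(draws >= observed_d)) / (draws.size + 1))


def csr_test(
    pattern: SpinePattern,
    nsim: int = 1000,
    t_grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    variant: str = "ang",
) -> tuple[CSRTestResult, KFunctionEstimate]:
    """MAD Monte-Carlo CSR test for a single dendrite.

    Each null draw re-places the observed number of spines uniformly on the
    same network and recomputes the Ang K-function and its MAD on the same
    t-grid, preserving the observed density λ.
    """
    rng = np.random.default_rng() if rng is None else rng
    if t_grid is None:
        t_grid = default_t_grid(pattern)
    est = empirical_k(pattern, t_grid, variant=variant)
    d_obs = mad_statistic(est).d
    draws = np.empty(nsim)
    for i in range(nsim):
        sim = simulate_csr(pattern.network, pattern.n, rng)
        draws[i] = mad_statistic(empirical_k(sim, t_grid, variant=variant)).d
    return (
        CSRTestResult(
            dendrite_id=pattern.dendrite_id,
            observed_d=d_obs,
            draws=draws,
            nsim=nsim,
            p_value=mc_pvalue(d_obs, draws),
            n=pattern.n,
            total_length=pattern.network.total_length,
        ),
        est,
    )


def pointwise_envelope(
    net: LinearNetwork,
    n: int,
    nsim: int,
    t_grid: np.ndarray,
    level: float = 0.05,
    rng: np.random.Generator | None = None,
    variant: str = "ang",
    keep_paths: bool = False,
) -> Envelope:
    """Per-t simulation envelope from CSR re-simulations.

    With nsim = 1000 and level 0.05 the band runs between the 50th smallest
    and 50th largest simulated K value at every t (a two-sided 10% test).
    """
    if not (0 < level < 0.5):
        raise ValidationError("level must lie in (0, 0.5)")
    if nsim < 20:
        raise ValidationError("nsim must be at least 20 for a meaningful envelope")
    rng = np.random.default_rng() if rng is None else rng
    paths = np.empty((nsim, len(t_grid)))
    for i in range(nsim):
        sim = simulate_csr(net, n, rng)
        paths[i] = empirical_k(sim, t_grid, variant=variant).k_hat
    r = int(np.ceil(level * nsim))
    ordered = np.sort(paths, axis=0)
    return Envelope(
        t_grid=np.asarray(t_grid),
        lower=ordered[r - 1],
        upper=ordered[nsim - r],
        nsim=nsim,
        level=level,
        k_paths=paths if keep_paths else None,
    )


# ------------------------------------------------------------------- q-values
def storey_qvalues(
    p_values,
    lambda_grid: np.ndarray | None = None,
    method: str = "storey",
) -> QValueResult:
    """Storey q-values with smoothed π0 estimation.

    π0(λ) = #{p > λ} / (m(1−λ)) is computed over the λ grid (default 0.05 to
    0.95 in steps of 0.05), smoothed by a cubic fit, and evaluated at the
    largest λ; q_i = min_{j: p_j ≥ p_i} π0 · m · p_j / rank_j, clipped to
    [0, 1].  ``method="bh"`` gives Benjamini–Hochberg (π0 = 1).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        if lambda_grid is None:
            lambda_grid = np.arange(0.05, 0.96, 0.05)
        lam = np.asarray(lambda_grid, dtype=float)
        pi0_lam = np.array([np.mean(p > l) / (1 - l) for l in lam])
        if lam.size >= 4:
            coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, deg=3)
            pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
        else:
            pi0 = float(pi0_lam.mean())
        pi0 = float(np.clip(pi0, 1.0 / m if m else 1e-8, 1.0))
    else:
        raise ValidationError(f"unknown method {method!r}")

    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return QValueResult(p_values=p, pi0=pi0, q_values=q, method=method)


# ------------------------------------------------------------------- batching
@dataclass
class BatchResult:
    tests: list[CSRTestResult]
    qvalues: QValueResult
    estimates: list[KFunctionEstimate] = field(default_factory=list)

    def as_dataframe(self) -> pd.DataFrame:
        rows = [
            dict(
                dendrite_id=t.dendrite_id,
                n=t.n,
                total_length=t.total_length,
                d=t.observed_d,
                p=t.p_value,
                q=q,
            )
            for t, q in zip(self.tests, self.qvalues.q_values)
        ]
        return pd.DataFrame(rows)


def csr_test_batch(
    patterns,
    nsim: int = 1000,
    rng: np.random.Generator | None = None,
    variant: str = "ang",
    qvalue_method: str = "storey",
    keep_estimates: bool = False,
) -> BatchResult:
    """Run the MAD CSR test on every dendrite and pool p-values into q-values.

    Patterns with fewer than 2 spines are skipped with a logged warning.
    Fully deterministic given the generator state.
    """
    rng = np.random.default_rng() if rng is None else rng
    tests: list[CSRTestResult] = []
    estimates: list[KFunctionEstimate] = []
    for pat in patterns:
        if pat.n < 2:
            logger.warning("skipping dendrite %s with N=%d < 2", pat.dendrite_id, pat.n)
            continue
        res, est = csr_test(pat, nsim=nsim, rng=rng, variant=variant)
        tests.append(res)
        if keep_estimates:
            estimates.append(est)
    pvals = np.array([t.p_value for t in tests])
    qres = storey_qvalues(pvals, method=qvalue_method)
    return BatchResult(tests=tests, qvalues=qres, estimates=estimates)


# ------------------------------------------------------------- Q-Q diagnostics
def sd_cdf(net: LinearNetwork):
    """CDF of soma distance under uniform-on-network placement.

    F(s) = (length of network at soma distance ≤ s) / ℓ_T, exact and piecewise
    linear from segment geometry.  Returns a callable with ``.inverse``.
    """
    depth = net.node_depth
    starts = depth[net.seg_parent]
    L = net.seg_length
    lT = net.total_length
    breaks = np.unique(np.concatenate([starts, starts + L, [0.0]]))

    def F(s):
        s = np.asarray(s, dtype=float)
        val = np.clip(s[..., None] - starts, 0.0, L).sum(axis=-1) / lT
        return val if val.ndim else float(val)

    Fb = np.atleast_1d(F(breaks))

    def inverse(q):
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValidationError("quantile levels must lie in [0, 1]")
        val = np.interp(q, Fb, breaks)
        return val if val.ndim else float(val)

    F.inverse = inverse
    F.breaks = breaks
    return F


def qq_points(pattern: SpinePattern, n_quantiles: int | None = None) -> QQDiagnostic:
    """Observed vs. theoretical soma-distance quantiles for one dendrite.

    Observed quantiles at plotting positions (i − 0.5)/N are compared to the
    exact inverse CDF of SD under CSR; points near y = x support the CSR null.
    A purely graphical diagnostic — no p-value is attached.
    """
    if pattern.n < 2:
        raise ValidationError("Q-Q diagnostic requires at least 2 spines")
    sd = np.sort([s.soma_distance for s in pattern.spines])
    if n_quantiles is None or n_quantiles >= pattern.n:
        obs = sd
        pos = (np.arange(1, pattern.n + 1) - 0.5) / pattern.n
    else:
        pos = (np.arange(1, n_quantiles + 1) - 0.5) / n_quantiles
        obs = np.quantile(sd, pos)
    theo = sd_cdf(pattern.network).inverse(pos)
    return QQDiagnostic(observed=obs, theoretical=np.asarray(theo))
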