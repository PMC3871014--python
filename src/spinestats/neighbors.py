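"""Nearest-neighbor type features, balanced sampling, and the multinomial
logistic regression (MLR) that predicts a spine's type from its neighborhood.

Each spine's predictor vector has length 7: the types of its three nearest
neighbors along the dendrite, each dummy-coded on two indicators —
(1,0) mushroom, (0,1) stubby, (0,0) thin — plus DIV entered as its numeric
value (7, 14 or 21).  Mushroom (category 0) is the reference category:
log(P(y=1)/P(y=0)) = β₁·X and log(P(y=2)/P(y=0)) = β₂·X, with the intercept
as the first element of each β.  A "Bayes factor" P(Y=i|X)/P(Y=i) compares
the neighborhood-informed prediction with the base rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    ConvergenceError,
    SampleShortageError,
    ValidationError,
)
from .network import SpinePattern, nearest_neighbors

logger = logging.getLogger(__name__)

TYPE_CODES = {"mushroom": 0, "stubby": 1, "thin": 2}
TYPE_DUMMY = {"mushroom": (1, 0), "stubby": (0, 1), "thin": (0, 0)}
FEATURE_NAMES = ("N1-Var1", "N1-Var2", "N2-Var1", "N2-Var2", "N3-Var1", "N3-Var2", "DIV")


@dataclass
class NeighborFeatures:
    """Design matrix and response for the neighbor-type MLR."""

    X: np.ndarray  # (n, 7) without intercept
    y: np.ndarray  # (n,) ints per TYPE_CODES
    distances: np.ndarray  # (n, k) neighbor distances, diagnostic only
    meta: pd.DataFrame  # experiment, div, dendrite_id, x, y per row
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.y)


def dummy_code(spine_type: str) -> tuple[int, int]:
    try:
        return TYPE_DUMMY[spine_type]
    except KeyError:
        raise ValidationError(f"unknown spine type {spine_type!r}") from None


def build_neighbor_features(patterns, k: int = 3) -> NeighborFeatures:
    """One feature row per spine with at least k neighbors on its own tree.

    Neighbors are found by network distance within the spine's dendrite only;
    inter-spine distances are recorded for diagnostics (e.g. the 3rd-neighbor
    distance histogram) but are not predictors.  Spines on dendrites with
    fewer than k other spines are excluded with a logged count.
    """
    if isinstance(patterns, SpinePattern):
        patterns = [patterns]
    rows_X, rows_y, rows_d, meta = [], [], [], []
    excluded = 0
    for pat in patterns:
        if pat.n < k + 1:
            excluded += pat.n
            continue
        dist = pat.pairwise_distances()
        for i, s in enumerate(pat.spines):
            nbrs = nearest_neighbors(pat, i, k, dist_matrix=dist)
            feat: list[float] = []
            for j, _ in nbrs:
                feat.extend(dummy_code(pat.spines[j].spine_type))
            feat.append(float(s.div))
            rows_X.append(feat)
            rows_y.append(TYPE_CODES[s.spine_type])
            rows_d.append([d for _, d in nbrs])
            xy = s.xy if s.xy is not None else tuple(pat.network.location_xy(s.location))
            meta.append(
                dict(
                    experiment=s.experiment,
                    div=s.div,
                    dendrite_id=pat.dendrite_id,
                    x=xy[0],
                    y=xy[1] if len(xy) > 1 else 0.0,
                )
            )
    if excluded:
        logger.warning("excluded %d spines with fewer than %d same-tree neighbors", excluded, k)
    return NeighborFeatures(
        X=np.asarray(rows_X, dtype=float).reshape(-1, 2 * k + 1),
        y=np.asarray(rows_y, dtype=int),
        distances=np.asarray(rows_d, dtype=float).reshape(-1, k),
        meta=pd.DataFrame(meta, columns=["experiment", "div", "dendrite_id", "x", "y"]),
        n_excluded=excluded,
    )


@dataclass
class BalancedSample:
    indices: np.ndarray
    n_per_type: int
    margin: float
    seed: int | None = None


def _eligibility_mask(features: NeighborFeatures, window, margin: float) -> np.ndarray:
    eligible = np.ones(features.n, dtype=bool)
    if window is not None:
        xmin, xmax, ymin, ymax = window
        x = features.meta["x"].to_numpy()
        yy = features.meta["y"].to_numpy()
        eligible = (
            (x - xmin >= margin)
            & (xmax - x >= margin)
            & (yy - ymin >= margin)
            & (ymax - yy >= margin)
        )
    return eligible


def eligible_counts(
    features: NeighborFeatures,
    window: tuple[float, float, float, float] | None,
    margin: float = 10.0,
) -> dict[str, int]:
    """Spines per type that remain eligible after the border-margin filter."""
    eligible = _eligibility_mask(features, window, margin)
    return {
        name: int(np.sum(eligible & (features.y == code)))
        for name, code in TYPE_CODES.items()
    }


def sample_balanced(
    features: NeighborFeatures,
    window: tuple[float, float, float, float] | None,
    n_per_type: int,
    margin: float = 10.0,
    rng: np.random.Generator | None = None,
) -> BalancedSample:
    """Equal-count random sample per spine type, away from the image border.

    Spines closer than ``margin`` (μm) to any window edge are ineligible, so
    their neighbors are unlikely to fall outside the imaged plane.  Raises
    :class:`SampleShortageError` naming the first type with too few eligible
    spines.
    """
    rng = np.random.default_rng() if rng is None else rng
    eligible = _eligibility_mask(features, window, margin)
    picks = []
    for name, code in TYPE_CODES.items():
        idx = np.flatnonzero(eligible & (features.y == code))
        if len(idx) < n_per_type:
            raise SampleShortageError(name, len(idx), n_per_type)
        picks.append(rng.choice(idx, size=n_per_type, replace=False))
    indices = np.sort(np.concatenate(picks)) if picks else np.array([], dtype=int)
    return BalancedSample(indices=indices, n_per_type=n_per_type, margin=margin)


@dataclass
class MLRModel:
    """Fitted (or published) multinomial logistic model, mushroom reference."""

    beta_stubby: np.ndarray  # length 8: intercept + 7 features
    beta_thin: np.ndarray
    se_stubby: np.ndarray | None = None
    se_thin: np.ndarray | None = None
    converged: bool = True
    llf: float | None = None
    #: covariance of the stacked parameter vector (stubby block then thin
    #: block, 16×16), when the Hessian is invertible
    cov_params: np.ndarray | None = None

    @classmethod
    def from_coefficients(cls, beta_stubby, beta_thin) -> "MLRModel":
        return cls(
            beta_stubby=np.asarray(beta_stubby, dtype=float),
            beta_thin=np.asarray(beta_thin, dtype=float),
        )


def fit_mlr(features: NeighborFeatures, indices=None, method: str = "bfgs") -> MLRModel:
    """Maximum-likelihood multinomial logistic fit (quasi-Newton by default).

    The problem is convex, so the estimate is deterministic given the data.
    All three response categories must be present.
    """
    X = features.X if indices is None else features.X[indices]
    y = features.y if indices is None else features.y[indices]
    present = np.unique(y)
    if len(present) < 3:
        raise ValidationError(
            f"all 3 spine types must appear in the response; found codes {present}"
        )
    exog = sm.add_constant(X, has_constant="add")
    model = sm.MNLogit(y, exog)
    result = model.fit(method=method, maxiter=500, disp=False)
    params = np.asarray(result.params)  # (8, 2): columns = categories 1, 2
    try:
        bse = np.asarray(result.bse)
        cov = np.asarray(result.cov_params())
    except ValueError:
        # singular Hessian (e.g. quasi-separation in a small balanced sample):
        # the point estimate is still usable, standard errors are not
        logger.warning("MLR standard errors unavailable (singular Hessian)")
        bse = None
        cov = None
    converged = bool(result.mle_retvals.get("converged", True))
    if not converged:
        logger.warning("MLR fit stopped before convergence (possible separation)")
    return MLRModel(
        beta_stubby=params[:, 0],
        beta_thin=params[:, 1],
        se_stubby=None if bse is None else bse[:, 0],
        se_thin=None if bse is None else bse[:, 1],
        converged=converged,
        llf=float(result.llf),
        cov_params=cov,
    )


def _validate_X(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != 7:
        raise ValidationError("X must have 7 entries (3 dummy pairs + DIV)")
    for pair in range(3):
        a, b = X[:, 2 * pair], X[:, 2 * pair + 1]
        ok = ((a == 1) & (b == 0)) | ((a == 0) & (b == 1)) | ((a == 0) & (b == 0))
        if not np.all(ok):
            raise ValidationError(f"invalid dummy pair in neighbor {pair + 1}")
    return X


def neighbor_vector(n1: str, n2: str, n3: str, div: int) -> np.ndarray:
    """Convenience builder of the 7-vector X from neighbor types and DIV."""
    return np.array(
        [*dummy_code(n1), *dummy_code(n2), *dummy_code(n3), float(div)]
    )


def predict_probs(model: MLRModel, X) -> dict[str, np.ndarray]:
    """Category probabilities for feature vector(s) X (without intercept).

    P(stubby) = e^{β₁X}/(1+e^{β₁X}+e^{β₂X}), P(thin) likewise with β₂, and
    P(mushroom) is the complement; the three always sum to 1.
    """
    X = _validate_X(X)
    Xc = np.column_stack([np.ones(len(X)), X])
    e1 = np.exp(Xc @ model.beta_stubby)
    e2 = np.exp(Xc @ model.beta_thin)
    denom = 1.0 + e1 + e2
    probs = {
        "mushroom": 1.0 / denom,
        "stubby": e1 / denom,
        "thin": e2 / denom,
    }
    if X.shape[0] == 1:
        probs = {k: float(v[0]) for k, v in probs.items()}
    return probs


def bayes_factor(model: MLRModel, X, priors: dict[str, float]) -> dict[str, float]:
    """P(Y=i | X) / P(Y=i): gain from neighborhood information over base rate.

    ``priors`` are the type frequencies over the full spine population of the
    experiment (not the balanced sample) and must sum to 1.
    """
    total = sum(priors.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"priors must sum to 1, got {total}")
    if any(v <= 0 for v in priors.values()):
        raise ValidationError("priors must be strictly positive")
    probs = predict_probs(model, X)
    return {t: probs[t] / priors[t] for t in priors}
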