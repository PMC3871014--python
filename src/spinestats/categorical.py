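"""Feature binning, contingency tables, and Poisson log-linear modelling.

Spine attributes (DIV, type, branch order, soma distance) are discretized,
cross-classified into a four-way count table f_ijkl, and modelled with a
Poisson log-linear GLM.  Forward stepwise selection by AIC identifies which
main effects and interactions matter; the drop-one table of the final model
ranks the retained interactions by their cost of omission.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import ConvergenceError, ValidationError
from .network import SpineRecord

DEFAULT_DIMS = ("div", "type", "bo", "sd")


# -------------------------------------------------------------------- binning
@dataclass
class BinnedFeatures:
    """Per-spine categorical features plus the SD breakpoints used."""

    frame: pd.DataFrame  # columns: div, type, bo, sd (all categorical)
    sd_breaks: tuple[float, ...]
    bo_cap: int = 5

    @property
    def n(self) -> int:
        return len(self.frame)


def bin_features(
    spines,
    sd_breaks: tuple[float, ...] | None = None,
    bo_cap: int = 5,
) -> BinnedFeatures:
    """Discretize spine attributes for contingency-table modelling.

    Branch orders of ``bo_cap`` or higher are pooled into a single
    "higher-order" category; soma distance is cut at ``sd_breaks`` (default:
    the empirical quartiles of the pooled SD values, giving categories
    Q1–Q4).
    """
    if isinstance(spines, pd.DataFrame):
        df = spines
    else:
        rows = [
            dict(
                div=s.div,
                type=s.spine_type,
                branch_order=s.branch_order,
                soma_distance=s.soma_distance,
                experiment=s.experiment,
            )
            for s in spines
        ]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no spines to bin")
    if (df["soma_distance"] < 0).any():
        raise ValidationError("negative soma distance")
    if sd_breaks is None:
        sd_breaks = tuple(np.quantile(df["soma_distance"], [0.25, 0.5, 0.75]))
    if any(nxt <= prev for prev, nxt in zip(sd_breaks[:-1], sd_breaks[1:])):
        raise ValidationError("sd_breaks must be strictly ascending")

    bo_labels = [str(i) for i in range(1, bo_cap)] + [f"{bo_cap}+"]
    bo = np.minimum(df["branch_order"], bo_cap)
    bo_cat = pd.Categorical(
        [bo_labels[b - 1] for b in bo], categories=bo_labels, ordered=True
    )
    sd_labels = [f"Q{i}" for i in range(1, len(sd_breaks) + 2)]
    sd_idx = np.searchsorted(np.asarray(sd_breaks), df["soma_distance"], side="left")
    sd_cat = pd.Categorical(
        [sd_labels[i] for i in sd_idx], categories=sd_labels, ordered=True
    )
    out = pd.DataFrame(
        dict(
            div=pd.Categorical(df["div"].astype(str), categories=["7", "14", "21"], ordered=True),
            type=pd.Categorical(df["type"], categories=["mushroom", "stubby", "thin"]),
            bo=bo_cat,
            sd=sd_cat,
        )
    )
    if "experiment" in df.columns:
        out["experiment"] = df["experiment"].to_numpy()
    return BinnedFeatures(frame=out, sd_breaks=tuple(sd_breaks), bo_cap=bo_cap)


# ----------------------------------------------------------- contingency table
@dataclass
class ContingencyTable:
    """Cross-classified counts over categorical dimensions."""

    counts: pd.Series  # MultiIndex over dims, integer values
    dims: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_array(self) -> np.ndarray:
        shape = [len(self.counts.index.get_level_values(d).unique()) for d in self.dims]
        return self.counts.to_numpy().reshape(shape)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per cell with a ``freq`` column."""
        df = self.counts.rename("freq").reset_index()
        return df

    def collapse(self, dims) -> "ContingencyTable":
        dims = tuple(dims)
        s = self.counts.groupby(level=list(dims), observed=False).sum()
        return ContingencyTable(counts=s, dims=dims)


def build_contingency(features, dims=DEFAULT_DIMS) -> ContingencyTable:
    """Count spines in every cell of the cross-classification over ``dims``.

    Accepts :class:`BinnedFeatures` or any DataFrame of categorical columns.
    Cells with no observations are kept with count 0.
    """
    frame = features.frame if isinstance(features, BinnedFeatures) else features
    dims = tuple(dims)
    for d in dims:
        if d not in frame.columns:
            raise ValidationError(f"dimension {d!r} not among features")
    counts = frame.groupby(list(dims), observed=False).size().astype(int)
    return ContingencyTable(counts=counts, dims=dims)


def chi_square_2way(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2-way table.

    Returns (X², df, p).  Accepts a 2-D array, DataFrame, or a 2-dimensional
    :class:`ContingencyTable`.
    """
    if isinstance(table, ContingencyTable):
        if len(table.dims) != 2:
            raise ValidationError("chi_square_2way needs a 2-dimensional table")
        arr = table.to_array()
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("table must be 2-dimensional")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("zero row or column margin")
    res = scipy.stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# -------------------------------------------------------------- log-linear fit
@dataclass
class LoglinearFit:
    terms: tuple[str, ...]
    params: pd.Series
    deviance: float
    aic: float
    k: int
    llf: float
    fitted: np.ndarray
    result: object = field(repr=False, default=None)


def _check_hierarchy(terms) -> None:
    mains = {t for t in terms if ":" not in t}
    for t in terms:
        if ":" in t:
            for piece in itertools.combinations(sorted(t.split(":")), 1):
                if piece[0] not in mains:
                    raise ValidationError(
                        f"non-hierarchical model: {t} requires main effect {piece[0]}"
                    )
            parts = sorted(t.split(":"))
            if len(parts) > 2:
                twoway = {
                    tt for tt in terms if ":" in tt and len(tt.split(":")) == 2
                }
                twoway = {":".join(sorted(tt.split(":"))) for tt in twoway}
                for a, b in itertools.combinations(parts, 2):
                    if f"{a}:{b}" not in twoway:
                        raise ValidationError(
                            f"non-hierarchical model: {t} requires {a}:{b}"
                        )


def fit_loglinear(table: ContingencyTable, terms) -> LoglinearFit:
    """Maximum-likelihood Poisson log-linear fit of cell counts.

    ``terms`` are patsy-style factor terms over the table's dimensions, e.g.
    ``["div", "type", "div:type"]``; they must form a hierarchical model.
    Treatment (reference-level) coding is used throughout.  AIC is computed as
    2k − 2·logL with k the number of estimated coefficients.
    """
    terms = tuple(terms)
    _check_hierarchy(terms)
    df = table.to_frame()
    rhs = " + ".join(terms) if terms else "1"
    model = smf.glm(f"freq ~ {rhs}", data=df, family=sm.families.Poisson())
    try:
        result = model.fit(maxiter=200)
    except Exception as exc:  # statsmodels raises several flavors
        raise ConvergenceError(f"Poisson fit failed for terms {terms}: {exc}") from exc
    if not result.converged:
        raise ConvergenceError(f"Poisson IRLS did not converge for terms {terms}")
    k = len(result.params)
    llf = float(result.llf)
    return LoglinearFit(
        terms=terms,
        params=result.params,
        deviance=float(result.deviance),
        aic=2 * k - 2 * llf,
        k=k,
        llf=llf,
        fitted=np.asarray(result.fittedvalues),
        result=result,
    )


# ------------------------------------------------------------------- stepwise
@dataclass
class StepwiseTrace:
    steps: list[tuple[str, float, float]]  # (term added, AIC before, AIC after)
    final: LoglinearFit
    drop_one: pd.DataFrame  # columns: term, df, deviance, aic


def _candidate_interactions(dims, order):
    return [":".join(c) for c in itertools.combinations(dims, order)]


def _removable_terms(terms):
    """Terms whose removal keeps the model hierarchical."""
    out = []
    for t in terms:
        parts = set(t.split(":"))
        needed = any(
            parts < set(o.split(":")) for o in terms if o != t and ":" in o
        ) or (":" not in t and any(t in o.split(":") for o in terms if ":" in o))
        if not needed:
            out.append(t)
    return out


def stepwise_aic(table: ContingencyTable, max_order: int = 2) -> StepwiseTrace:
    """Forward stepwise selection of a hierarchical log-linear model by AIC.

    Starts from the all-main-effects model (the mutual-independence baseline
    standard for contingency tables, which also avoids hierarchy deadlocks
    when an association has uniform margins) and adds interactions up to
    ``max_order`` (2 or 3), each step taking the candidate with the largest
    AIC decrease; stops when no candidate lowers the AIC.
    The drop-one table reports, for every term of the final model that can be
    removed without breaking hierarchy, the df, deviance and AIC of the model
    without it (rows sorted by increasing AIC, i.e. decreasing importance).
    """
    if max_order not in (2, 3):
        raise ValidationError("max_order must be 2 or 3")
    dims = table.dims
    pool = _candidate_interactions(dims, 2)
    if max_order == 3:
        pool += _candidate_interactions(dims, 3)

    current: list[str] = list(dims)
    fit = fit_loglinear(table, current)
    steps: list[tuple[str, float, float]] = []
    while True:
        best_term, best_fit = None, None
        for cand in pool:
            if cand in current:
                continue
            trial = current + [cand]
            try:
                _check_hierarchy(trial)
            except ValidationError:
                continue
            try:
                f = fit_loglinear(table, trial)
            except ConvergenceError:
                continue
            if best_fit is None or f.aic < best_fit.aic:
                best_term, best_fit = cand, f
        if best_fit is None or best_fit.aic >= fit.aic:
            break
        steps.append((best_term, fit.aic, best_fit.aic))
        current.append(best_term)
        fit = best_fit

    rows = []
    for t in _removable_terms(current):
        reduced = fit_loglinear(table, [x for x in current if x != t])
        rows.append(
            dict(
                term=t,
                df=fit.k - reduced.k,
                deviance=reduced.deviance,
                aic=reduced.aic,
            )
        )
    drop = pd.DataFrame(rows, columns=["term", "df", "deviance", "aic"])
    if not drop.empty:
        drop = drop.sort_values("aic").reset_index(drop=True)
    return StepwiseTrace(steps=steps, final=fit, drop_one=drop)
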