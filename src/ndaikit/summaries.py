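"""Object-level index statistics and regression-based index evaluation.

The per-object summary mirrors what a phenotyping pipeline reports per
image: mean, standard deviation (population, n denominator), coefficient
of variation, range and a histogram of index values over plant pixels
only. The standard deviation doubles as a within-object pigment
heterogeneity measure.

Index evaluation regresses each index's object means on measured
anthocyanin concentration (µg g⁻¹ FW) by ordinary least squares —
concentration is the predictor, the index the response — fitting both a
linear and a quadratic model and selecting by AIC. Reported metrics:

* R² = 1 − RSS/TSS
* RMSE = sqrt(RSS / n)  (index units; n denominator)
* AIC = n·ln(RSS/n) + 2k, the least-squares form with k = number of
  regression coefficients + 1 (the error variance counts as a parameter)
* p-value of the overall F-test.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .imaging import IndexMap

#: Indices with a bounded theoretical range get a fixed default histogram range.
BOUNDED_RANGES = {"NDAI": (-1.0, 1.0), "NARI": (-1.0, 1.0)}


@dataclasses.dataclass(frozen=True)
class IndexSummary:
    """Statistics of one index over the plant pixels of one image."""

    name: str
    mean: float
    sd: float
    cv: float | None  # sd/mean; None when mean == 0
    min: float
    max: float
    n_valid: int
    n_undefined: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """One fitted index-versus-concentration OLS model.

    ``coefficients`` are in increasing polynomial order:
    (intercept, slope) for linear, (intercept, slope, curvature) for
    quadratic. ``warning`` flags degraded fits (e.g. quadratic infeasible
    and replaced by linear).
    """

    model: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]
    r_squared: float
    rmse: float
    aic: float
    p_value: float
    n: int
    conc_range: tuple[float, float]
    index_range: tuple[float, float]
    warning: str | None = None

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted polynomial at concentration(s) ``conc``."""
        c = np.asarray(conc, dtype=float)
        out = np.zeros_like(c)
        for p, coef in enumerate(self.coefficients):
            out = out + coef * c**p
        return float(out) if np.isscalar(conc) else out


def index_summary(
    index_map: IndexMap,
    bins: int = 50,
    hist_range: tuple[float, float] | None = None,
) -> IndexSummary:
    """Summarize an index map over its valid (plant) pixels.

    The histogram defaults to the index's theoretical range when bounded
    (NDAI: [−1, 1]) and to the data range otherwise. Raises ``ValueError``
    on a map with no valid pixels.
    """
    vals = index_map.valid_values
    if vals.size == 0:
        raise ValueError("index map has no valid pixels to summarize")
    mean = float(vals.mean())
    sd = float(vals.std())  # population sd
    cv = sd / mean if mean != 0 else None
    if hist_range is None:
        hist_range = BOUNDED_RANGES.get(index_map.name)
    counts, edges = np.histogram(vals, bins=bins, range=hist_range)
    # values exactly outside an explicit range fall off the histogram;
    # fold them into the edge bins so counts always sum to n_valid
    if counts.sum() != vals.size:
        counts[0] += int((vals < edges[0]).sum())
        counts[-1] += int((vals > edges[-1]).sum())
    return IndexSummary(
        name=index_map.name,
        mean=mean,
        sd=sd,
        cv=cv,
        min=float(vals.min()),
        max=float(vals.max()),
        n_valid=int(vals.size),
        n_undefined=index_map.n_undefined,
        hist_counts=counts,
        hist_edges=edges,
    )


def _design(conc: np.ndarray, model: str) -> np.ndarray:
    cols = [np.ones_like(conc), conc]
    if model == "quadratic":
        cols.append(conc**2)
    return np.column_stack(cols)


def fit_index_model(
    conc: np.ndarray, idx: np.ndarray, model: str = "linear"
) -> RegressionResult:
    """OLS fit of index values on anthocyanin concentration.

    ``model`` is ``"linear"`` (2 coefficients) or ``"quadratic"`` (3).
    Needs at least one more observation than coefficients; a constant
    predictor or constant response is degenerate and raises ``ValueError``.
    """
    conc = np.asarray(conc, dtype=float)
    idx = np.asarray(idx, dtype=float)
    if model not in ("linear", "quadratic"):
        raise ValueError(f"model must be linear or quadratic, got {model!r}")
    if conc.shape != idx.shape or conc.ndim != 1:
        raise ValueError("conc and idx must be matched 1-D arrays")
    n = conc.size
    n_coef = 2 if model == "linear" else 3
    if n < n_coef + 1:
        raise ValueError(f"{model} fit needs at least {n_coef + 1} points, got {n}")
    if np.ptp(conc) == 0:
        raise ValueError("constant predictor: concentrations show no variation")
    if np.ptp(idx) == 0:
        raise ValueError("zero-variance response: index values are constant")

    X = _design(conc, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits trip kurtosistest warnings
        res = sm.OLS(idx, X).fit()
    rss = float(res.ssr)
    tss = float(((idx - idx.mean()) ** 2).sum())
    r_squared = 1.0 - rss / tss
    rmse = float(np.sqrt(rss / n))
    k = n_coef + 1  # error variance counted as a parameter
    with np.errstate(divide="ignore"):
        aic = float(n * np.log(rss / n) + 2 * k) if rss > 0 else -np.inf
    p_value = float(res.f_pvalue)
    return RegressionResult(
        model=model,
        coefficients=tuple(float(c) for c in res.params),
        r_squared=max(0.0, min(1.0, r_squared)),
        rmse=rmse,
        aic=aic,
        p_value=p_value if np.isfinite(p_value) else 0.0,
        n=n,
        conc_range=(float(conc.min()), float(conc.max())),
        index_range=(float(idx.min()), float(idx.max())),
    )


def select_model(conc: np.ndarray, idx: np.ndarray) -> RegressionResult:
    """Fit linear and quadratic models; keep the lower-AIC one.

    Ties (|ΔAIC| < 1e-9) go to the linear model. When the sample is too
    small for a quadratic fit, the linear fit is returned with a warning
    flag.
    """
    linear = fit_index_model(conc, idx, "linear")
    n = np.asarray(conc).size
    if n < 4:
        return dataclasses.replace(
            linear, warning="quadratic fit infeasible (n < 4); linear model returned"
        )
    quadratic = fit_index_model(conc, idx, "quadratic")
    if quadratic.aic < linear.aic - 1e-9:
        return quadratic
    return linear


def compare_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Evaluate every index column of an evaluation table against concentration.

    ``table`` must carry a ``concentration_ug_g`` column (and optionally
    ``sample_id``); every other column is treated as an index. Returns one
    row per index with columns ``Index, Model, R2, RMSE, AIC, p``, sorted
    by ascending AIC (best model first). Row order of the input is
    irrelevant.
    """
    if table.empty:
        raise ValueError("evaluation table is empty")
    if "concentration_ug_g" not in table.columns:
        raise ValueError("evaluation table lacks a 'concentration_ug_g' column")
    if table["concentration_ug_g"].isna().any():
        raise ValueError("evaluation table has missing concentrations")
    index_cols = [
        c for c in table.columns if c not in ("sample_id", "concentration_ug_g")
    ]
    if not index_cols:
        raise ValueError("evaluation table has no index columns")
    conc = table["concentration_ug_g"].to_numpy(dtype=float)
    rows = []
    for col in index_cols:
        fit = select_model(conc, table[col].to_numpy(dtype=float))
        rows.append(
            {
                "Index": col,
                "Model": fit.model,
                "R2": fit.r_squared,
                "RMSE": fit.rmse,
                "AIC": fit.aic,
                "p": fit.p_value,
            }
        )
    out = pd.DataFrame(rows).sort_values("AIC", kind="mergesort")
    return out.reset_index(drop=True)


def predict_concentration(fit: RegressionResult, idx_value: float) -> float:
    """Invert a fitted calibration curve: index value → concentration.

    Restricted to the fitted concentration range; the curve must be
    strictly monotone over that range and the index value must lie within
    the fitted index range (no extrapolation).
    """
    lo, hi = fit.conc_range
    grid = np.linspace(lo, hi, 512)
    curve = fit.predict(grid)
    diffs = np.diff(curve)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError(
            "fitted curve is not monotone over the calibration range; inversion ambiguous"
        )
    cmin, cmax = float(curve.min()), float(curve.max())
    if not (cmin - 1e-12 <= idx_value <= cmax + 1e-12):
        raise ValueError(
            f"index value {idx_value} outside fitted range [{cmin:.6g}, {cmax:.6g}]"
        )
    idx_value = min(max(idx_value, cmin), cmax)  # absorb float fuzz at endpoints
    f = lambda c: fit.predict(c) - idx_value
    fa, fb = f(lo), f(hi)
    if fa == 0:
        return lo
    if fb == 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))
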