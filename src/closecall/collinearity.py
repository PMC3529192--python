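"""Multicollinearity screening with variance inflation factors computed
under the random-effect structure of the analysis (individual nested in
group).

For each predictor j a linear mixed regression of j on the remaining
predictors is fitted with random intercepts for group and for
individual-within-group; VIF_j = 1 / (1 - R²_j) where R²_j is, by
default, the fixed-effects share of the fixed + residual variance.
Predictors are then eliminated greedily, largest VIF first, until all
remaining VIFs fall at or below the threshold (2.5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VIF_CAP = 1e6
DEFAULT_THRESHOLD = 2.5


@dataclass
class VifReport:
    vifs: dict[str, float]
    retained: list[str]
    dropped: list[str] = field(default_factory=list)
    threshold: float | None = None
    #: VIF table recomputed at each elimination round
    history: list[dict[str, float]] = field(default_factory=list)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R² of y on X (with intercept) via least squares."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = np.sum((y - y.mean()) ** 2)
    if sst <= 0:
        raise ValueError("constant response in VIF regression")
    return float(1.0 - np.sum(resid**2) / sst)


def _mixed_r2(data: pd.DataFrame, response: str, others: list[str],
              group_col: str, individual_col: str,
              include_random_variance: bool) -> float:
    """Fixed-effects R² from a mixed regression of one predictor on the rest."""
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    formula = f"{response} ~ " + " + ".join(others)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data[group_col],
                            re_formula="1",
                            vc_formula={"ind": f"0 + C({individual_col})"})
        # ML, not REML: in the zero-random-variance limit the ML residual
        # variance reproduces the OLS R² convention exactly
        result = model.fit(reml=False, method="lbfgs", maxiter=200)

    fe = np.asarray(result.fe_params)
    exog = np.asarray(result.model.exog)
    fitted_fixed = exog @ fe
    var_fixed = float(np.var(fitted_fixed))
    var_resid = float(result.scale)
    denom = var_fixed + var_resid
    if include_random_variance:
        # cov_re / vcomp are already on the response scale in statsmodels
        var_group = float(np.asarray(result.cov_re)[0, 0])
        var_ind = float(np.sum(result.vcomp))
        denom += var_group + var_ind
    if denom <= 0:
        return 1.0
    return min(var_fixed / denom, 1.0)


def mixed_model_vif(table: pd.DataFrame, predictors: list[str],
                    group_col: str = "group_id",
                    individual_col: str = "individual_id",
                    include_random_variance: bool = False) -> VifReport:
    """VIF of each predictor under the nested random-effect structure.

    Falls back to the ordinary least-squares R² (with a warning) when
    the mixed fit fails; exactly collinear predictors yield a finite
    capped VIF with a warning.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    if table[individual_col].nunique() < 2:
        raise ValueError("need at least two individuals")
    data = table[[group_col, individual_col, *predictors]].copy()
    for p in predictors:
        if np.isclose(data[p].std(ddof=0), 0.0):
            raise ValueError(f"constant predictor {p!r}")
        # standardize for numerical stability; VIF is scale-invariant
        data[p] = (data[p] - data[p].mean()) / data[p].std(ddof=0)

    vifs: dict[str, float] = {}
    for p in predictors:
        others = [q for q in predictors if q != p]
        y = data[p].to_numpy(dtype=float)
        X = data[others].to_numpy(dtype=float)
        try:
            r2 = _mixed_r2(data, p, others, group_col, individual_col,
                           include_random_variance)
        except Exception as exc:  # singular design, optimizer failure, ...
            warnings.warn(f"mixed VIF fit failed for {p!r} ({exc}); "
                          "falling back to OLS R²")
            r2 = min(_ols_r2(y, X), 1.0)
        if r2 >= 1.0 - 1.0 / VIF_CAP:
            warnings.warn(f"predictor {p!r} is (near-)perfectly collinear; "
                          f"VIF capped at {VIF_CAP:g}")
            vif = VIF_CAP
        else:
            vif = 1.0 / (1.0 - r2)
        vifs[p] = max(vif, 1.0)
    return VifReport(vifs=vifs, retained=predictors, threshold=None,
                     history=[dict(vifs)])


def select_noncollinear(table: pd.DataFrame, predictors: list[str],
                        threshold: float = DEFAULT_THRESHOLD,
                        **vif_kwargs) -> VifReport:
    """Greedy elimination: drop the largest-VIF predictor above the
    threshold, recompute, repeat. Ties break to the earliest predictor
    in the input ordering."""
    order = {p: i for i, p in enumerate(predictors)}
    remaining = list(predictors)
    dropped: list[str] = []
    history: list[dict[str, float]] = []
    vifs: dict[str, float] = {}
    while True:
        if len(remaining) < 2:
            warnings.warn("fewer than two predictors remain; stopping")
            break
        report = mixed_model_vif(table, remaining, **vif_kwargs)
        vifs = report.vifs
        history.append(dict(vifs))
        worst = max(remaining, key=lambda p: (vifs[p], -order[p]))
        if vifs[worst] <= threshold:
            break
        remaining.remove(worst)
        dropped.append(worst)
    return VifReport(vifs=vifs, retained=remaining, dropped=dropped,
                     threshold=threshold, history=history)
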