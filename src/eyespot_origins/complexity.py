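"""Network complexity vs. trait complexity: ordinary least-squares test.

Per species, the number of eyespot-associated genes with focal expression
(network complexity) is regressed against the maximum number of colored
rings in adult eyespots (trait complexity); the slope is tested with the
standard regression F statistic on (1, n - 2) degrees of freedom.  This is
plain OLS by design — no phylogenetic correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ComplexityRecord", "RegressionResult", "complexity_regression"]


@dataclass(frozen=True)
class ComplexityRecord:
    species: str
    n_genes: int
    n_rings: int

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_rings < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    r_squared: float

    def __str__(self) -> str:
        return (
            f"F_{{{self.df[0]},{self.df[1]}}} = {self.f_statistic:.2f}, "
            f"p = {self.p_value:.3f} (slope {self.slope:.3f}, R^2 {self.r_squared:.3f})"
        )


def complexity_regression(records) -> RegressionResult:
    """OLS of ring count on expressed-gene count, with an F test.

    ``records`` is a list of :class:`ComplexityRecord` or a DataFrame with
    ``n_genes`` and ``n_rings`` columns.  Perfectly collinear data yield
    R^2 = 1 with an infinite F (reported as ``inf``, p = 0).
    """
    if isinstance(records, pd.DataFrame):
        x = records["n_genes"].to_numpy(dtype=float)
        y = records["n_rings"].to_numpy(dtype=float)
    else:
        x = np.array([r.n_genes for r in records], dtype=float)
        y = np.array([r.n_rings for r in records], dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 records for a regression F test")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid_ss = float(model.ssr)
    if resid_ss <= 1e-12 * max(float(model.centered_tss), 1.0):
        return RegressionResult(
            slope=float(model.params[1]), intercept=float(model.params[0]),
            f_statistic=float("inf"), df=(1, n - 2), p_value=0.0, r_squared=1.0,
        )
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        f_statistic=float(model.fvalue),
        df=(1, n - 2),
        p_value=float(model.f_pvalue),
        r_squared=float(model.rsquared),
    )
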