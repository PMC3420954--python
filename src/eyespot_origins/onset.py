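"""Temporal onset of gene expression: logistic curves and the delta test.

Expression of a gene in future eyespot centers is scored 0/1 per wing
compartment across a continuous developmental-stage axis.  For each gene a
logistic curve ``P(x) = 1 / (1 + exp(-(a + b x)))`` is fitted by maximum
likelihood.  The timing difference between two genes is

    delta = | AUC_A - AUC_B |

the absolute difference in areas under the two fitted curves over a shared
stage range.  Significance comes from a mixed bootstrap embodying the null
of one common onset curve: each pseudo-gene is rebuilt from half of gene
A's and half of gene B's observations, refitted, and delta recomputed;
the p-value is ``(1 + #{delta_null >= delta_obs}) / (1 + n_boot)``.

Perfect separation (a stage threshold splitting 0s from 1s exactly) drives
the ML slope to infinity; the slope is capped at |b| <= 50, which leaves
the AUC essentially unchanged once the curve saturates inside the range
but keeps every resample fittable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LogisticCurve",
    "DeltaResult",
    "fit_logistic",
    "curve_auc",
    "delta_obs",
    "bootstrap_delta_test",
    "pairwise_onset_report",
    "significance_stars",
]

SLOPE_CAP = 50.0
MIN_ROWS = 4

#: Fig-2-style significance annotations.
STAR_THRESHOLDS = ((1e-4, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class LogisticCurve:
    """Fitted curve ``P(x) = expit(a + b x)`` over the observed stage range."""

    a: float
    b: float
    lo: float
    hi: float
    flagged: bool = False  #: capped slope or degenerate data

    @property
    def midpoint(self) -> float:
        """Stage at which P crosses 1/2 (undefined direction if b == 0)."""
        if self.b == 0:
            return np.nan
        return -self.a / self.b

    def predict(self, x) -> np.ndarray:
        z = np.clip(self.a + self.b * np.asarray(x, dtype=float), -700, 700)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class DeltaResult:
    delta_obs: float
    p_value: float
    n_boot: int
    seed: int
    null_quantiles: tuple[float, float, float]  #: 5%, 50%, 95% of delta_null
    n_redrawn: int = 0


def _nll_and_derivs(a, b, x, y):
    z = np.clip(a + b * x, -700, 700)
    p = 1.0 / (1.0 + np.exp(-z))
    resid = p - y
    w = p * (1.0 - p)
    ga, gb = resid.sum(), (resid * x).sum()
    haa = w.sum()
    hab = (w * x).sum()
    hbb = (w * x * x).sum()
    return ga, gb, haa, hab, hbb


def _fit_intercept_only(b, x, y, max_iter=60):
    """Profile MLE of a for a fixed (capped) slope; concave 1-D Newton."""
    a = 0.0
    for _ in range(max_iter):
        z = np.clip(a + b * x, -700, 700)
        p = 1.0 / (1.0 + np.exp(-z))
        g = (p - y).sum()
        h = (p * (1.0 - p)).sum()
        if h < 1e-12:
            break
        step = g / h
        a -= np.clip(step, -20.0, 20.0)
        if abs(step) < 1e-10:
            break
    return float(a)


def fit_logistic(data, gene: str | None = None) -> LogisticCurve:
    """ML logistic regression of expression on developmental stage.

    ``data`` is a DataFrame with ``stage`` and ``expression`` columns
    (optionally restricted to ``gene`` via its ``gene`` column), or any
    pair of array-likes ``(stages, expression)``.  Deterministic.  Fewer
    than 4 rows is an error; one-sided outcomes and perfect separation
    return capped-slope boundary curves flagged as such.
    """
    if isinstance(data, pd.DataFrame):
        if gene is not None:
            data = data[data["gene"] == gene]
            if data.empty:
                raise KeyError(f"gene {gene!r} not present in the dataset")
        x = data["stage"].to_numpy(dtype=float)
        y = data["expression"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in data)
    if x.size < MIN_ROWS:
        raise ValueError(f"need at least {MIN_ROWS} observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("stages must be finite")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("expression must be binary 0/1")
    lo, hi = float(x.min()), float(x.max())
    span = (hi - lo) or 1.0

    if y.min() == y.max():
        # One outcome only: boundary curve saturated at that outcome over
        # the observed range, with the capped slope.
        if y[0] == 1:
            mid = lo - 10.0 / SLOPE_CAP
        else:
            mid = hi + 10.0 / SLOPE_CAP
        return LogisticCurve(-SLOPE_CAP * mid, SLOPE_CAP, lo, hi, flagged=True)
    if lo == hi:
        # Mixed outcomes at a single stage: flat curve at the observed rate.
        pbar = float(y.mean())
        return LogisticCurve(float(np.log(pbar / (1 - pbar))), 0.0, lo, hi, flagged=True)

    # Newton-Raphson on (a, b); fall back to the capped-slope profile when
    # the slope escapes the cap (perfect or quasi-separation).
    pbar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    a, b = np.log(pbar / (1 - pbar)), 0.0
    for _ in range(100):
        ga, gb, haa, hab, hbb = _nll_and_derivs(a, b, x, y)
        det = haa * hbb - hab * hab
        if det < 1e-12 * max(haa * hbb, 1e-300) or haa < 1e-12:
            break
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        limit = 10.0 / span
        db = float(np.clip(db, -limit * 4, limit * 4))
        da = float(np.clip(da, -40.0, 40.0))
        a, b = a - da, b - db
        if abs(b) > SLOPE_CAP:
            break
        if abs(da) + abs(db) * span < 1e-10:
            return LogisticCurve(float(a), float(b), lo, hi)
    sb = SLOPE_CAP if b >= 0 else -SLOPE_CAP
    # Compare the capped-slope profile against the last interior iterate.
    a_cap = _fit_intercept_only(sb, x, y)

    def nll(aa, bb):
        z = np.clip(aa + bb * x, -700, 700)
        return float(np.sum(np.log1p(np.exp(-z)) + (1 - y) * z))

    if abs(b) <= SLOPE_CAP and nll(a, b) < nll(a_cap, sb):
        return LogisticCurve(float(a), float(b), lo, hi)
    return LogisticCurve(a_cap, float(sb), lo, hi, flagged=True)


def curve_auc(curve: LogisticCurve, lo: float, hi: float) -> float:
    """Analytic area under the logistic curve over ``[lo, hi]``.

    The antiderivative of ``expit(a + b x)`` is ``softplus(a + b x) / b``;
    with ``b == 0`` the curve is constant and the area is ``P * (hi - lo)``.
    """
    if not lo < hi:
        raise ValueError("integration range must satisfy lo < hi")
    a, b = curve.a, curve.b
    if b == 0:
        return float(curve.predict(lo)) * (hi - lo)
    softplus = lambda z: np.logaddexp(0.0, z)
    return float((softplus(a + b * hi) - softplus(a + b * lo)) / b)


def _shared_range(xa, xb):
    lo = min(float(np.min(xa)), float(np.min(xb)))
    hi = max(float(np.max(xa)), float(np.max(xb)))
    if lo == hi:  # degenerate: widen symmetrically so the AUC is defined
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def delta_obs(dataA, dataB) -> float:
    """Absolute AUC difference between two genes' fitted curves.

    The integration range is the pooled min..max of the two genes' observed
    stages, matching the pooled resampling of the null.
    """
    xa, ya = _as_xy(dataA)
    xb, yb = _as_xy(dataB)
    lo, hi = _shared_range(xa, xb)
    ca = fit_logistic((xa, ya))
    cb = fit_logistic((xb, yb))
    return abs(curve_auc(ca, lo, hi) - curve_auc(cb, lo, hi))


def _as_xy(data):
    if isinstance(data, pd.DataFrame):
        return (
            data["stage"].to_numpy(dtype=float),
            data["expression"].to_numpy(dtype=float),
        )
    x, y = data
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def bootstrap_delta_test(
    dataA, dataB, n_boot: int = 10_000, seed: int = 0
) -> DeltaResult:
    """Mixed-bootstrap test of equal onset timing between two genes.

    Each replicate builds pseudo-gene A* from ``floor(nA/2)`` rows of A plus
    ``nA - floor(nA/2)`` rows of B, and B* from ``floor(nB/2)`` rows of A
    plus the remainder from B — every half drawn independently with
    replacement — then refits both curves and records delta_null.  A
    replicate whose resample cannot be fitted is redrawn (and counted);
    more than 50% redraws aborts with advice to collect larger samples.
    """
    xa, ya = _as_xy(dataA)
    xb, yb = _as_xy(dataB)
    nA, nB = xa.size, xb.size
    if nA < MIN_ROWS or nB < MIN_ROWS:
        raise ValueError(f"each gene needs at least {MIN_ROWS} observations")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    lo, hi = _shared_range(xa, xb)
    d_obs = abs(
        curve_auc(fit_logistic((xa, ya)), lo, hi)
        - curve_auc(fit_logistic((xb, yb)), lo, hi)
    )

    rng = np.random.default_rng(seed)
    halfA, halfB = nA // 2, nB // 2
    null = np.empty(n_boot)
    n_redrawn = 0
    for i in range(n_boot):
        while True:
            ia1 = rng.integers(0, nA, size=halfA)
            ib1 = rng.integers(0, nB, size=nA - halfA)
            ia2 = rng.integers(0, nA, size=halfB)
            ib2 = rng.integers(0, nB, size=nB - halfB)
            xs1 = np.concatenate([xa[ia1], xb[ib1]])
            ys1 = np.concatenate([ya[ia1], yb[ib1]])
            xs2 = np.concatenate([xa[ia2], xb[ib2]])
            ys2 = np.concatenate([ya[ia2], yb[ib2]])
            try:
                c1 = fit_logistic((xs1, ys1))
                c2 = fit_logistic((xs2, ys2))
            except ValueError:
                n_redrawn += 1
                if n_redrawn > n_boot // 2:
                    raise ValueError(
                        "more than half of bootstrap resamples were unfittable; "
                        "collect larger samples per gene"
                    ) from None
                continue
            null[i] = abs(curve_auc(c1, lo, hi) - curve_auc(c2, lo, hi))
            break
    p = (1 + int(np.sum(null >= d_obs))) / (1 + n_boot)
    q = np.quantile(null, [0.05, 0.5, 0.95])
    return DeltaResult(
        delta_obs=float(d_obs), p_value=float(p), n_boot=n_boot, seed=seed,
        null_quantiles=(float(q[0]), float(q[1]), float(q[2])),
        n_redrawn=n_redrawn,
    )


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def pairwise_onset_report(
    data: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Delta test for each ordered gene pair, pooled across compartments.

    Returns one row per pair with delta_obs, the bootstrap p-value and
    its star annotation (*** p<0.0001, ** p<0.01, * p<0.05, ns).
    Compartment identity is ignored after pooling.
    """
    genes = set(data["gene"])
    rng = np.random.default_rng(seed)
    rows = []
    for gA, gB in pairs:
        for g in (gA, gB):
            if g not in genes:
                raise KeyError(f"gene {g!r} not present in the onset dataset")
        sub_a = data[data["gene"] == gA]
        sub_b = data[data["gene"] == gB]
        res = bootstrap_delta_test(
            sub_a, sub_b, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1))
        )
        rows.append({
            "gene_a": gA,
            "gene_b": gB,
            "delta_obs": res.delta_obs,
            "p_value": res.p_value,
            "stars": significance_stars(res.p_value),
            "n_a": int((data["gene"] == gA).sum()),
            "n_b": int((data["gene"] == gB).sum()),
        })
    return pd.DataFrame(rows)
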