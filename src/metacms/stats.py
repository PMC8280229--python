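"""Odds-ratio machinery for 2x2 contingency tables.

Two estimators are provided: the sample (cross-product) odds ratio with
a Woolf log-normal confidence interval, and the conditional maximum-
likelihood estimate under the noncentral hypergeometric model with an
exact conditional interval (the Fisher's-exact-test convention, the
package default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from metacms.core_io import CMS_CLASSES


@dataclass(frozen=True)
class TwoByTwo:
    """Cell counts; rows = exposure, columns = outcome.

    Layout::

        a  b     exposed:     outcome+, outcome-
        c  d     unexposed:   outcome+, outcome-
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    method: str


def odds_ratio(
    t: TwoByTwo, method: str = "conditional_mle", alpha: float = 0.05
) -> OddsRatioResult:
    """Odds ratio with a (1 - alpha) confidence interval.

    ``method="sample"``: cross-product ratio ad/bc, Woolf CI; if any
    cell is 0 the Haldane correction (+0.5 to every cell) is applied
    with a warning. ``method="conditional_mle"``: noncentral
    hypergeometric MLE with an exact conditional interval.

    Raises
    ------
    ValueError
        On a zero margin (a row or column summing to 0), or an unknown
        method.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: odds ratio undefined")
    if method == "sample":
        a, b, c, d = (float(v) for v in (t.a, t.b, t.c, t.d))
        if min(a, b, c, d) == 0:
            warnings.warn(
                "zero cell: applying Haldane 0.5 correction", stacklevel=2
            )
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        est = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = norm.ppf(1 - alpha / 2)
        lo, hi = np.exp(np.log(est) - z * se), np.exp(np.log(est) + z * se)
        return OddsRatioResult(float(est), float(lo), float(hi), "sample")
    if method == "conditional_mle":
        res = _scipy_odds_ratio(arr, kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        return OddsRatioResult(
            float(res.statistic), float(ci.low), float(ci.high), "conditional_mle"
        )
    raise ValueError(f"unknown method {method!r}")


def proportion_shift(
    calls_primary: pd.Series | list,
    calls_metastasis: pd.Series | list,
    method: str = "conditional_mle",
) -> pd.DataFrame:
    """Per-class enrichment of metastases versus primaries.

    For each class k, builds the 2x2 table (metastasis vs primary) x
    (class k vs rest) over *confident* calls only ("NA" dropped) and
    reports the odds ratio with its CI. Returns a table indexed by
    class with columns odds_ratio, ci_low, ci_high, n_metastasis,
    n_primary.
    """
    prim = pd.Series(list(calls_primary))
    met = pd.Series(list(calls_metastasis))
    prim = prim[prim.isin(CMS_CLASSES)]
    met = met[met.isin(CMS_CLASSES)]
    if prim.empty or met.empty:
        raise ValueError("need confident calls in both cohorts")
    rows = []
    for cls in CMS_CLASSES:
        a = int((met == cls).sum())
        b = int((met != cls).sum())
        c = int((prim == cls).sum())
        d = int((prim != cls).sum())
        if (a + c) == 0:  # class absent everywhere: OR undefined
            rows.append(
                {
                    "class": cls,
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_metastasis": a,
                    "n_primary": c,
                }
            )
            continue
        res = odds_ratio(TwoByTwo(a, b, c, d), method=method)
        rows.append(
            {
                "class": cls,
                "odds_ratio": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_metastasis": a,
                "n_primary": c,
            }
        )
    return pd.DataFrame(rows).set_index("class")
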