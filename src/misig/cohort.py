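"""Cohort-level aggregation of per-genus boundaries and inflection estimates.

Across many genera the per-genus AF/ANI boundary corners and inflection
points form distributions whose mean, median, quartiles and 95% CI of the
mean summarise how tight the genus-level signal is across taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demarcation import Boundary
from .errors import MisigError
from .inflection import InflectionEstimate

__all__ = ["CohortSummary", "summarize", "summarize_cohort_report"]


@dataclass(frozen=True, slots=True)
class CohortSummary:
    n: int
    mean: float
    median: float
    q25: float
    q75: float
    ci95_mean: tuple[float, float] | None


def summarize(values: Sequence[float]) -> CohortSummary:
    """Mean, median, linear-interpolation quartiles and t-based 95% CI.

    With a single value the CI is undefined (None); quartiles use linear
    interpolation between order statistics (the common spreadsheet default).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise MisigError("no values: nothing to summarize")
    mean = float(x.mean())
    q25, median, q75 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    if x.size >= 2:
        sem = float(x.std(ddof=1)) / np.sqrt(x.size)
        t = float(stats.t.ppf(0.975, df=x.size - 1))
        ci = (mean - t * sem, mean + t * sem)
    else:
        ci = None
    return CohortSummary(n=int(x.size), mean=mean, median=median, q25=q25, q75=q75, ci95_mean=ci)


_ROWS = ("af_boundary", "ani_boundary", "af_inflection", "ani_inflection")


def summarize_cohort_report(
    boundaries: Sequence[Boundary],
    inflections: Sequence[InflectionEstimate] = (),
) -> pd.DataFrame:
    """Four-row summary table: AF/ANI of boundaries and accepted inflections.

    Only accepted inflection estimates are aggregated; if all were rejected
    the inflection rows are null and a warning is emitted.
    """
    if not boundaries:
        raise MisigError("no values: boundary list is empty")
    accepted = [e for e in inflections if e.accepted]
    if inflections and not accepted:
        warnings.warn("all inflection estimates rejected; inflection rows are null")
    series: dict[str, Sequence[float]] = {
        "af_boundary": [b.af_boundary for b in boundaries],
        "ani_boundary": [b.ani_boundary for b in boundaries],
        "af_inflection": [e.af_star for e in accepted],
        "ani_inflection": [e.ani_star for e in accepted],
    }
    rows = []
    for name in _ROWS:
        vals = series[name]
        if vals:
            s = summarize(vals)
            lo, hi = s.ci95_mean if s.ci95_mean else (np.nan, np.nan)
            rows.append(
                {"quantity": name, "n": s.n, "mean": s.mean, "median": s.median,
                 "q25": s.q25, "q75": s.q75, "ci95_low": lo, "ci95_high": hi}
            )
        else:
            rows.append(
                {"quantity": name, "n": 0, "mean": np.nan, "median": np.nan,
                 "q25": np.nan, "q75": np.nan, "ci95_low": np.nan, "ci95_high": np.nan}
            )
    return pd.DataFrame(rows).set_index("quantity")
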