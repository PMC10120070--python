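"""Site-level summaries of robot-wing approach counts.

Field trials present free-flying butterflies with paired robotic wing
models — one with strong linear polarization, one depolarized — at
several field sites and per colour treatment.  Responses are aggregated
per site, and the per-site differences (polarized minus depolarized) are
tested against zero with a one-sample Student's t-test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

TREATMENTS = ("blue", "yellow", "red")


def site_differences(table: pd.DataFrame, treatment: str) -> pd.Series:
    """Per-site signed difference (polarized - depolarized) for one
    treatment, indexed by site."""
    if treatment not in set(table["treatment"]):
        raise ValueError(
            f"treatment {treatment!r} not present "
            f"(have {sorted(set(table['treatment']))})"
        )
    sub = table[table["treatment"] == treatment]
    grouped = sub.groupby("site_id")[["n_polarized", "n_depolarized"]].sum()
    return grouped["n_polarized"] - grouped["n_depolarized"]


def one_sample_t(differences) -> tuple[float, int, float]:
    """One-sample Student's t-test of the mean difference against zero.

    Returns (t, df, two-sided p) with t = mean / (sd / sqrt(n)),
    df = n - 1, sd the n-1 sample standard deviation.
    """
    d = np.asarray(list(differences), dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample standard deviation: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    from scipy.stats import t as t_dist

    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), df, float(p)


def approach_proportion(n_depolarized_total: int, n_total: int) -> int:
    """Percentage of approaches to the depolarized model, truncated to a
    whole percent (113 of 183 reports as 61)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_depolarized_total <= n_total):
        raise ValueError("n_depolarized_total must be in [0, n_total]")
    return int(100 * n_depolarized_total // n_total)
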