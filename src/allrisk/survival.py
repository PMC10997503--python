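"""Product-limit (Kaplan-Meier) estimation and group comparison.

Risk tables come from ``lifelines``; the product-limit recursion and the
Greenwood variance are computed directly from the event table so the
curve object carries exactly the columns the package exports (time,
n_risk, n_event, survival, Greenwood SE). Evaluation at an arbitrary
time uses the right-continuous step convention; ties between events and
censorings at the same time count the events first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import survival_table_from_events


@dataclass
class KMCurve:
    """Kaplan-Meier estimate with Greenwood pointwise variance."""

    times: np.ndarray  # distinct event times, sorted
    survival: np.ndarray  # S(t) just after each event time
    greenwood_se: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    max_observed_time: float

    def at(self, t, return_truncation_flag: bool = False):
        """S(t) by right-continuous step lookup. Beyond the last observed
        time the last value carries forward; ``return_truncation_flag``
        additionally reports whether follow-up ended before ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:  # no events observed
            s = np.ones_like(t_arr)
        else:
            idx = np.searchsorted(self.times, t_arr, side="right") - 1
            s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        truncated = t_arr > self.max_observed_time
        if np.isscalar(t):
            s, truncated = float(s[0]), bool(truncated[0])
        if return_truncation_flag:
            return s, truncated
        return s

    def se_at(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:
            se = np.zeros_like(t_arr)
        else:
            idx = np.searchsorted(self.times, t_arr, side="right") - 1
            se = np.where(idx >= 0, self.greenwood_se[np.clip(idx, 0, None)], 0.0)
        return float(se[0]) if np.isscalar(t) else se

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "se": self.greenwood_se,
            }
        )


def km_estimate(outcomes) -> KMCurve:
    """Product-limit estimate with Greenwood variance.

    Raises ``ValueError`` on an empty input or negative times.
    """
    if len(outcomes) == 0:
        raise ValueError("km_estimate needs at least one outcome")
    time = np.array([o.time for o in outcomes], dtype=float)
    event = np.array([o.event for o in outcomes], dtype=int)
    if np.any(time < 0):
        raise ValueError("negative survival times")
    table = survival_table_from_events(time, event)
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    t = table.index.to_numpy(dtype=float)
    keep = d > 0
    t, d, n = t[keep], d[keep], n[keep]
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d))); at S == 0 the
    # variance is 0 by convention.
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    cum = np.cumsum(terms)
    var = np.where(surv > 0, surv**2 * cum, 0.0)
    return KMCurve(
        times=t,
        survival=surv,
        greenwood_se=np.sqrt(var),
        n_risk=n.astype(int),
        n_event=d.astype(int),
        max_observed_time=float(time.max()),
    )


def logrank(outcome_groups):
    """k-sample log-rank test; returns ``(statistic, df, p)``.

    Raises ``ValueError`` with fewer than two non-empty groups.
    """
    groups = [g for g in outcome_groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("logrank needs at least two non-empty groups")
    time = np.concatenate([[o.time for o in g] for g in groups])
    event = np.concatenate([[o.event for o in g] for g in groups])
    label = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    res = multivariate_logrank_test(time, label, event)
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


def plot_km_groups(group_outcomes: dict, path, horizon: float | None = None, title: str = ""):
    """Overlay KM curves for labeled groups and save to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for label, outcomes in group_outcomes.items():
        curve = km_estimate(outcomes)
        t = np.r_[0.0, np.repeat(curve.times, 2)]
        s = np.r_[1.0, 1.0, np.repeat(curve.survival, 2)[:-1]]
        ax.plot(t, s, drawstyle="default", label=f"{label} (n={len(outcomes)})")
    if horizon is not None:
        ax.axvline(horizon, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("years from end of induction")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
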