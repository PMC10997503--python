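"""Concordance probability estimate (CPE), cutpoint optimization into
ordered risk groups, clinical-algorithm rules engine, and cross-tabulation.

The Gonen-Heller concordance probability estimate is a model-based
concordance measure computed from pairwise differences of Cox linear
predictors; unlike Harrell's C it does not touch the censored times
directly. Risk-group cutpoints are chosen by exhaustive search over
score quantiles: each candidate partition is re-expressed as ordered
group indicators, a Cox model is refit on those indicators, and the CPE
of the refit's fitted linear predictors is the objective (the CPE is
defined on a model's linear predictors, so the objective refits rather
than scoring the raw categorized values; the objective function is
isolated so alternatives can be swapped in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from . import cox
from .errors import ConfigError, UnclassifiedError, UndefinedResultError
from .survival import km_estimate

DEFAULT_LABELS = ("Low", "Standard", "Intermediate", "High")


# ---------------------------------------------------------------------------
# CPE


def cpe(scores, include_ties: bool = False) -> float:
    """Gonen-Heller concordance probability estimate.

    Average over unordered pairs of ``1 / (1 + exp(-|eta_i - eta_j|))``.
    Pairs with exactly tied scores are excluded from numerator and
    denominator by default (``include_ties=True`` instead credits them
    0.5). Returns 0.5 when every score is tied. Always >= 0.5.
    """
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if n < 2:
        raise ValueError("cpe needs at least two scores")
    # collapse to unique values: pair contributions depend only on values
    vals, counts = np.unique(s, return_counts=True)
    k = len(vals)
    if k == 1:
        return 0.5
    numer = 0.0
    denom = 0.0
    chunk = 512
    for lo in range(0, k, chunk):
        hi = min(lo + chunk, k)
        diff = np.abs(vals[lo:hi, None] - vals[None, :])
        w = counts[lo:hi, None].astype(float) * counts[None, :].astype(float)
        mask = vals[lo:hi, None] < vals[None, :]  # each unordered distinct pair once
        numer += float((w / (1.0 + np.exp(-diff)) * mask).sum())
        denom += float((w * mask).sum())
    if include_ties:
        tied_pairs = float((counts * (counts - 1) / 2).sum())
        numer += 0.5 * tied_pairs
        denom += tied_pairs
    if denom == 0:
        return 0.5
    return numer / denom


def _cpe_grouped(group_eta: np.ndarray, group_counts: np.ndarray,
                 include_ties: bool = False) -> float:
    """CPE when scores take one value per ordered group (closed form)."""
    numer = 0.0
    denom = 0.0
    k = len(group_eta)
    for i in range(k):
        for j in range(i + 1, k):
            w = float(group_counts[i]) * float(group_counts[j])
            d = abs(group_eta[i] - group_eta[j])
            if d == 0 and not include_ties:
                continue
            numer += w * (0.5 if d == 0 else 1.0 / (1.0 + np.exp(-d)))
            denom += w
    if include_ties:
        tied = float((group_counts * (group_counts - 1) / 2).sum())
        numer += 0.5 * tied
        denom += tied
    return 0.5 if denom == 0 else numer / denom


# ---------------------------------------------------------------------------
# cutpoints


@dataclass
class CutpointSet:
    """Strictly increasing thresholds partitioning a score into ordered
    risk groups (left-open, right-closed intervals)."""

    cutpoints: list[float]
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        cuts = list(self.cutpoints)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.labels) != len(cuts) + 1:
            raise ValueError("need exactly one more label than cutpoints")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"cutpoints": list(self.cutpoints), "labels": list(self.labels)}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CutpointSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(cutpoints=list(d["cutpoints"]), labels=tuple(d["labels"]))


def default_cutpoints() -> CutpointSet:
    """The shipped concordance-maximizing cutpoints of the published
    eight-covariate index (-1.377, -0.589, 0.093)."""
    from .index import load_builtin

    cs = load_builtin("published_cog")
    return CutpointSet(cutpoints=list(cs.cutpoints), labels=tuple(cs.labels))


def assign_risk_group(score: float, cuts: CutpointSet) -> str:
    """Label i such that c_{i-1} < score <= c_i (c_0 = -inf, c_k = +inf).

    A score exactly on a cutpoint falls in the lower group.
    """
    idx = int(np.searchsorted(np.asarray(cuts.cutpoints, dtype=float), score, side="left"))
    return cuts.labels[idx]


def assign_risk_groups(scores, cuts: CutpointSet) -> np.ndarray:
    idx = np.searchsorted(np.asarray(cuts.cutpoints, dtype=float), np.asarray(scores), side="left")
    return np.asarray(cuts.labels, dtype=object)[idx]


def find_cutpoints(scores, outcomes, k_groups: int = 4,
                   grid_quantile_step: float = 0.02,
                   min_group_frac: float = 0.05,
                   labels: tuple[str, ...] | None = None,
                   tie_method: str = "efron",
                   include_ties: bool = True):
    """Exhaustive CPE-maximizing search for k-1 ordered cutpoints.

    Candidate thresholds are empirical score quantiles on a
    ``grid_quantile_step`` grid. For each feasible (k-1)-tuple the
    scores are collapsed to ordered group indicators, a Cox model is
    refit on the indicators, and the CPE of its fitted linear predictors
    is the objective. Deterministic given inputs; candidates leaving any
    group below ``min_group_frac`` (or empty) are skipped.

    The objective uses the tie-inclusive CPE (within-group pairs credited
    0.5 over the full pair denominator, the canonical Gonen-Heller
    convention). Excluding tied pairs makes the search degenerate: it
    rewards carving off minimum-size extreme groups, because shrinking a
    group removes its 0.5-credit within-pairs from the average instead
    of counting them; ``include_ties=False`` remains available.

    Returns ``(CutpointSet, achieved_cpe)``.
    """
    if k_groups < 2:
        raise ConfigError("k_groups must be >= 2")
    if min_group_frac * k_groups > 1.0:
        raise ConfigError(
            f"min_group_frac={min_group_frac} infeasible for {k_groups} groups"
        )
    if labels is None:
        labels = DEFAULT_LABELS if k_groups == 4 else tuple(f"G{i+1}" for i in range(k_groups))
    s = np.asarray(scores, dtype=float)
    n = len(s)
    qs = np.arange(grid_quantile_step, 1.0 - 1e-12, grid_quantile_step)
    candidates = np.unique(np.quantile(s, qs))
    if len(candidates) < k_groups - 1:
        raise ConfigError("not enough distinct candidate thresholds")
    s_sorted = np.sort(s)
    min_count = max(1, int(np.ceil(min_group_frac * n)))
    outcomes = list(outcomes)

    best = None
    for combo in combinations(range(len(candidates)), k_groups - 1):
        cuts = candidates[list(combo)]
        # group sizes via positions in the sorted scores
        edges = np.searchsorted(s_sorted, cuts, side="right")
        counts = np.diff(np.r_[0, edges, n])
        if counts.min() < min_count:
            continue
        group = np.searchsorted(cuts, s, side="left")
        design = (group[:, None] >= np.arange(1, k_groups)[None, :]).astype(float)
        try:
            fit = cox.fit_cox(outcomes, design, tie_method=tie_method,
                              names=tuple(f"ge_{g}" for g in range(1, k_groups)))
        except Exception:
            continue
        eta = np.r_[0.0, np.cumsum(fit.coef)]  # one LP value per ordered group
        value = _cpe_grouped(eta, counts, include_ties=include_ties)
        if best is None or value > best[0] + 1e-12:
            best = (value, cuts)
    if best is None:
        raise ConfigError("no feasible cutpoint candidate satisfied the constraints")
    value, cuts = best
    return CutpointSet(cutpoints=[float(c) for c in cuts], labels=tuple(labels)), float(value)


# ---------------------------------------------------------------------------
# clinical rules engine


_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "in": lambda a, b: a in b,
    "is_missing": lambda a, b: a is None,
}


@dataclass
class ClinicalRules:
    """Ordered first-match-wins classification rules over patient fields.

    Each rule is ``{"label": str, "all": [{"field", "op", "value"}, ...]}``;
    a record matches when every condition holds. ``default`` labels
    records no rule matches (optional).
    """

    rules: list[dict]
    default: str | None = None
    name: str = "custom"

    def __post_init__(self):
        for rule in self.rules:
            if "label" not in rule or "all" not in rule:
                raise ConfigError("each rule needs 'label' and 'all'")
            for cond in rule["all"]:
                if cond.get("op") not in _OPS:
                    raise ConfigError(f"unknown rule operator {cond.get('op')!r}")

    @classmethod
    def from_json(cls, path) -> "ClinicalRules":
        with open(path) as fh:
            d = json.load(fh)
        return cls(rules=d["rules"], default=d.get("default"), name=d.get("name", "custom"))


def load_default_rules() -> ClinicalRules:
    """The shipped approximate clinical rules (config data; labeled
    approximate — the exact trial algorithm tables are not public)."""
    text = resources.files("allrisk.config").joinpath("clinical_rules_default.json").read_text()
    d = json.loads(text)
    return ClinicalRules(rules=d["rules"], default=d.get("default"), name=d.get("name", "default"))


def classify_cog_clinical(record, rules: ClinicalRules) -> str:
    """First matching rule's label; deterministic.

    A rule condition referencing a missing field (other than
    ``is_missing``) raises :class:`UnclassifiedError` naming the field;
    with no match, the default label is returned if configured.
    """
    for rule in rules.rules:
        matched = True
        for cond in rule["all"]:
            fname, op = cond["field"], cond["op"]
            if not hasattr(record, fname):
                raise UnclassifiedError(f"rule references unknown field {fname!r}", field=fname)
            value = getattr(record, fname)
            if value is None and op != "is_missing":
                raise UnclassifiedError(
                    f"record {getattr(record, 'id', '?')}: field {fname!r} is missing", field=fname
                )
            if not _OPS[op](value, cond.get("value")):
                matched = False
                break
        if matched:
            return rule["label"]
    if rules.default is None:
        raise UnclassifiedError("no rule matched and no default label is configured")
    return rules.default


# ---------------------------------------------------------------------------
# cross-tabulation


@dataclass
class CrossTab:
    """Contingency counts plus per-cell KM estimates at a horizon."""

    counts: pd.DataFrame  # rows: labels_a, cols: labels_b, with totals
    km: pd.DataFrame  # per-cell KM estimate at horizon (NaN when suppressed)
    km_se: pd.DataFrame
    horizon: float
    min_n: int

    def to_csv(self, path_prefix: str) -> None:
        self.counts.to_csv(f"{path_prefix}_counts.csv")
        self.km.to_csv(f"{path_prefix}_km.csv")
        self.km_se.to_csv(f"{path_prefix}_km_se.csv")


def crosstab_riskgroups(labels_a, labels_b, outcomes, horizon: float,
                        min_n: int = 25,
                        row_order=None, col_order=None) -> CrossTab:
    """Cross-tabulate two risk classifications with per-cell survival.

    Cells with fewer than ``min_n`` records have their KM estimate
    suppressed (reported as NaN), mirroring the reporting convention for
    unreliable small-cell estimates.
    """
    la = np.asarray(labels_a, dtype=object)
    lb = np.asarray(labels_b, dtype=object)
    if len(la) != len(lb) or len(la) != len(outcomes):
        raise ValueError("label vectors and outcomes must have equal length")
    rows = row_order if row_order is not None else sorted(set(la))
    cols = col_order if col_order is not None else sorted(set(lb))
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    km = pd.DataFrame(np.nan, index=rows, columns=cols, dtype=float)
    km_se = pd.DataFrame(np.nan, index=rows, columns=cols, dtype=float)
    outcomes = list(outcomes)
    for r in rows:
        for c in cols:
            mask = (la == r) & (lb == c)
            n_cell = int(mask.sum())
            counts.loc[r, c] = n_cell
            if n_cell == 0 or n_cell < min_n:
                continue
            cell = [outcomes[i] for i in np.flatnonzero(mask)]
            curve = km_estimate(cell)
            km.loc[r, c] = curve.at(horizon)
            km_se.loc[r, c] = curve.se_at(horizon)
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    return CrossTab(counts=counts, km=km, km_se=km_se, horizon=horizon, min_n=min_n)
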