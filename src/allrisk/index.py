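"""Prognostic-index scoring with published or fitted coefficient sets.

A prognostic index (PI) is the uncentered linear predictor of a Cox
model: the dot product of log-hazard-ratio coefficients with the
transformed covariates. Three coefficient sets ship as versioned config
data (``config/coefficients.json``):

* ``published_ukall`` — the UKALL equation applied externally
  (UKALL's CYTO_GR/CYTO_HR genetics indicators mapped to frg/urg),
* ``derived_ukall``   — the same model re-derived on the external cohort,
* ``published_cog``   — the eight-covariate COG index (PI_COG), shipped
  with its concordance-maximizing risk-group cutpoints.

Keeping published models as data rather than code constants makes model
updating a config change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import cox
from .transforms import CovariateVector, encode_covariates, encode_cohort

PROVENANCES = ("published_ukall", "derived_ukall", "published_cog", "fitted")


@dataclass
class CoefficientSet:
    """A named prognostic model: covariate names and log-hazard coefficients."""

    name: str
    terms: list[tuple[str, float]]
    provenance: str = "fitted"
    covariance: np.ndarray | None = None
    cutpoints: list[float] | None = None
    labels: list[str] | None = None

    def __post_init__(self):
        names = [t[0] for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        if not all(np.isfinite(t[1]) for t in self.terms):
            raise ValueError("coefficients must be finite")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.terms)

    @property
    def coef(self) -> np.ndarray:
        return np.array([t[1] for t in self.terms], dtype=float)

    @classmethod
    def from_fit(cls, fit: cox.CoxFit, name: str = "fitted") -> "CoefficientSet":
        return cls(
            name=name,
            terms=list(zip(fit.names, fit.coef.tolist())),
            provenance="fitted",
            covariance=fit.cov,
        )

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "provenance": self.provenance,
            "terms": [[n, c] for n, c in self.terms],
        }
        if self.covariance is not None:
            payload["covariance"] = np.asarray(self.covariance).tolist()
        if self.cutpoints is not None:
            payload["cutpoints"] = list(self.cutpoints)
        if self.labels is not None:
            payload["labels"] = list(self.labels)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        return cls(
            name=d["name"],
            terms=[(str(n), float(c)) for n, c in d["terms"]],
            provenance=d.get("provenance", "fitted"),
            covariance=(
                np.asarray(d["covariance"], dtype=float) if "covariance" in d else None
            ),
            cutpoints=d.get("cutpoints"),
            labels=d.get("labels"),
        )

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_builtin(name: str) -> CoefficientSet:
    """Load one of the shipped coefficient sets by name."""
    text = resources.files("allrisk.config").joinpath("coefficients.json").read_text()
    catalog = json.loads(text)
    if name not in catalog:
        raise KeyError(f"unknown builtin coefficient set {name!r}; have {sorted(catalog)}")
    return CoefficientSet.from_dict(catalog[name])


def score_pi(coeffs: CoefficientSet | cox.CoxFit, cov: CovariateVector) -> float:
    """Score one covariate vector: the uncentered linear predictor."""
    return cox.linear_predictor(coeffs, cov)


def hazard_ratios(coeffs: CoefficientSet | cox.CoxFit) -> pd.DataFrame:
    """Per-term hazard ratios exp(coefficient), with 95% Wald CIs when a
    covariance is available.

    Printed tables occasionally round from unrounded coefficients, so a
    hazard ratio recomputed from a rounded published coefficient can
    differ from a printed value in the last digit.
    """
    names = tuple(coeffs.names)
    beta = np.asarray(coeffs.coef, dtype=float)
    out = pd.DataFrame({"coef": beta, "hr": np.exp(beta)}, index=list(names))
    covm = getattr(coeffs, "covariance", None)
    if covm is None:
        covm = getattr(coeffs, "cov", None)
    if covm is not None:
        se = np.sqrt(np.diag(np.asarray(covm, dtype=float)))
        out["hr_lo"] = np.exp(beta - 1.96 * se)
        out["hr_hi"] = np.exp(beta + 1.96 * se)
    return out


def score_cohort(records, coeffs: CoefficientSet, cutpoint_set=None) -> tuple[pd.DataFrame, dict]:
    """Score a cohort with a coefficient set (complete-case).

    Returns ``(frame, excluded)``: a DataFrame with columns ``id`` and
    ``pi`` (plus ``risk_group`` when ``cutpoint_set`` is given), and the
    per-field counts of records excluded for missing covariates.
    """
    kept, X, excluded = encode_cohort(records, required=coeffs.names)
    pi = X @ coeffs.coef
    frame = pd.DataFrame({"id": [r.id for r in kept], "pi": pi})
    if cutpoint_set is not None:
        from .cutpoints import assign_risk_group

        frame["risk_group"] = [assign_risk_group(s, cutpoint_set) for s in pi]
    return frame, excluded
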