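"""Deterministic covariate transformations.

The model covariates are

* ``tau_d29``, ``tau_d8`` — negative natural log of the minimal residual
  disease (MRD) fraction, floored so that undetectable disease maps to a
  fixed maximum (13.8155... = -ln(1e-6), 13.82 at two decimals),
* ``frg`` / ``urg`` — favorable / unfavorable risk-genetics indicators,
* ``wbc_log`` — natural log of the presenting white blood cell count,
* ``cns2`` / ``cns3`` — central-nervous-system status dummies (CNS1 ref),
* ``age`` — age at diagnosis in years.

All MRD values are handled on the fraction scale (0.01% == 1e-4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .errors import MissingCovariateError

#: Canonical covariate order used throughout the package.
COVARIATE_NAMES = ("tau_d29", "tau_d8", "frg", "urg", "wbc_log", "cns2", "cns3", "age")

#: Default floor fraction assigned to undetectable MRD; -ln(1e-6) = 13.8155.
MRD_FLOOR_FRACTION = 1e-6
#: MRD below this fraction is treated as undetectable and floored.
MRD_CAP_THRESHOLD = 1e-5


def tau_mrd(
    mrd: float,
    floor_fraction: float = MRD_FLOOR_FRACTION,
    cap_threshold: float = MRD_CAP_THRESHOLD,
    base: float | None = None,
) -> float:
    """Negative-log MRD transform on the fraction scale.

    Values below ``cap_threshold`` (including exactly 0, i.e. undetectable
    disease) are assigned the transform of ``floor_fraction``, so the
    transform is capped at -ln(1e-6) = 13.8155 under the defaults. Higher
    tau means less residual disease.

    Parameters
    ----------
    mrd : float
        MRD as a fraction in [0, 1].
    floor_fraction : float
        Fraction substituted for undetectable values.
    cap_threshold : float
        Detection threshold below which the floor applies.
    base : float, optional
        Logarithm base; natural log when omitted.

    Raises
    ------
    ValueError
        If ``mrd`` lies outside [0, 1].
    """
    if not (0.0 <= mrd <= 1.0) or math.isnan(mrd):
        raise ValueError(f"MRD fraction must lie in [0, 1], got {mrd!r}")
    x = floor_fraction if mrd < cap_threshold else mrd
    value = -math.log(x)
    if base is not None:
        value /= math.log(base)
    return value


def wbc_log(wbc: float, base: float | None = None) -> float:
    """Log-transformed white blood cell count (x10^9/L); natural log default.

    Raises
    ------
    ValueError
        If ``wbc`` is not strictly positive.
    """
    if not wbc > 0 or math.isnan(wbc):
        raise ValueError(f"WBC must be > 0, got {wbc!r}")
    value = math.log(wbc)
    if base is not None:
        value /= math.log(base)
    return value


@dataclass(frozen=True)
class CovariateVector:
    """The transformed model covariates for one patient.

    Fields not needed by the active coefficient set may be ``None``;
    requesting them through :meth:`as_array` raises
    :class:`~allrisk.errors.MissingCovariateError`.
    """

    tau_d29: float | None = None
    tau_d8: float | None = None
    frg: float | None = None
    urg: float | None = None
    wbc_log: float | None = None
    cns2: float | None = None
    cns3: float | None = None
    age: float | None = None

    def __post_init__(self):
        if (self.cns2 or 0) + (self.cns3 or 0) > 1:
            raise ValueError("cns2 + cns3 must be <= 1")

    def as_array(self, names: tuple[str, ...] = COVARIATE_NAMES) -> np.ndarray:
        out = np.empty(len(names), dtype=float)
        for i, name in enumerate(names):
            value = getattr(self, name)
            if value is None:
                raise MissingCovariateError(name)
            out[i] = value
        return out

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(cls))


# Raw PatientRecord field backing each model covariate.
_SOURCE_FIELD = {
    "tau_d29": "d29_mrd",
    "tau_d8": "d8_mrd",
    "frg": "frg",
    "urg": "urg",
    "wbc_log": "wbc",
    "cns2": "cns",
    "cns3": "cns",
    "age": "age_years",
}


def encode_covariates(record, required: tuple[str, ...] | None = None) -> CovariateVector:
    """Build the transformed covariate vector for one patient record.

    ``required`` lists the covariate names the caller's coefficient set
    needs (default: all eight). A required covariate whose raw field is
    missing raises :class:`MissingCovariateError` naming the field;
    non-required missing covariates are stored as ``None``.
    """
    if required is None:
        required = COVARIATE_NAMES
    values: dict[str, float | None] = {}
    for name in COVARIATE_NAMES:
        raw = getattr(record, _SOURCE_FIELD[name])
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            if name in required:
                raise MissingCovariateError(_SOURCE_FIELD[name])
            values[name] = None
            continue
        if name == "tau_d29" or name == "tau_d8":
            values[name] = tau_mrd(raw)
        elif name == "wbc_log":
            values[name] = wbc_log(raw)
        elif name in ("frg", "urg"):
            values[name] = float(bool(raw))
        elif name == "cns2":
            values[name] = float(raw == "CNS2")
        elif name == "cns3":
            values[name] = float(raw == "CNS3")
        else:  # age
            values[name] = float(raw)
    return CovariateVector(**values)


def encode_cohort(
    records,
    required: tuple[str, ...] | None = None,
):
    """Encode many records; complete-case with exclusion bookkeeping.

    Returns ``(kept_records, matrix, excluded)`` where ``matrix`` is an
    (n_kept, len(required)) float array in ``required`` order and
    ``excluded`` maps raw field name -> count of records dropped for
    missing that field (first missing field wins).
    """
    if required is None:
        required = COVARIATE_NAMES
    kept, rows = [], []
    excluded: dict[str, int] = {}
    for rec in records:
        try:
            vec = encode_covariates(rec, required=required)
        except MissingCovariateError as err:
            excluded[err.field] = excluded.get(err.field, 0) + 1
            continue
        kept.append(rec)
        rows.append(vec.as_array(tuple(required)))
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, len(required)))
    return kept, matrix, excluded
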