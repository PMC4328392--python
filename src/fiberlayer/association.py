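"""Projection-composition vs infection-composition association.

Each animal contributes two log-ratio covariates:

* abundance ratio — ``log10((d_GL + c) / (d_GCL + c))`` of its layer label
  densities, the relative weight of glomerular- vs granule-cell-layer
  projections;
* infection ratio — ``log10((n_MRN + c) / (n_DRN + c))`` of its infected-cell
  counts in the two raphe nuclei (a fractional-composition form
  ``n_MRN / (n_MRN + n_DRN)`` is available as an alternative).

Pseudocounts ``c`` (1 cell for counts, 1e-4 μm²/100 μm² for densities)
stabilize the logs because real cohorts contain zeros; both are surfaced in
the result. The association is the Pearson correlation between the two
ratios across animals, with the standard t-based two-sided p-value.

A scatter-plot colour encoding maps the abundance log-ratio L (clipped to
[0, 1]) to RGB = (L, 0.8·(1−L), 1−L): granule-heavy animals appear
blue-green, glomerular-heavy animals red.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegreesOfFreedomError, InvalidInputError, UndefinedCorrelationError

__all__ = [
    "AnimalSummary",
    "LogRatio",
    "AssociationResult",
    "abundance_ratio",
    "infection_ratio",
    "correlate",
    "abundance_rgb",
    "DEFAULT_COUNT_PSEUDOCOUNT",
    "DEFAULT_DENSITY_PSEUDOCOUNT",
]

DEFAULT_COUNT_PSEUDOCOUNT = 1.0
DEFAULT_DENSITY_PSEUDOCOUNT = 1e-4


@dataclass(frozen=True)
class AnimalSummary:
    """Per-animal infection counts and layer label densities."""

    animal: str
    n_drn: float
    n_mrn: float
    d_gl: float
    d_gcl: float
    injection_target: str = ""

    def __post_init__(self) -> None:
        if min(self.n_drn, self.n_mrn, self.d_gl, self.d_gcl) < 0:
            raise InvalidInputError("counts and densities must be non-negative")


@dataclass(frozen=True)
class LogRatio:
    """A pseudocount-stabilized base-10 log ratio."""

    value: float
    pseudocount: float


def _log_ratio(num: float, den: float, pseudocount: float, what: str) -> LogRatio:
    if not pseudocount > 0:
        raise InvalidInputError(f"{what} pseudocount must be > 0, got {pseudocount}")
    if num < 0 or den < 0:
        raise InvalidInputError(f"{what} values must be non-negative, got {num}, {den}")
    return LogRatio(
        value=float(np.log10((num + pseudocount) / (den + pseudocount))),
        pseudocount=float(pseudocount),
    )


def abundance_ratio(
    d_gl: float, d_gcl: float, pseudocount: float = DEFAULT_DENSITY_PSEUDOCOUNT
) -> LogRatio:
    """log10 of GL over GCL label density, pseudocount-stabilized."""
    return _log_ratio(d_gl, d_gcl, pseudocount, "density")


def infection_ratio(
    n_mrn: float,
    n_drn: float,
    pseudocount: float = DEFAULT_COUNT_PSEUDOCOUNT,
    form: str = "log_ratio",
) -> LogRatio:
    """Relative MRN vs DRN infection level.

    ``form="log_ratio"`` (default) gives log10((n_MRN+c)/(n_DRN+c)),
    mirroring the abundance covariate; ``form="fraction"`` gives the
    composition (n_MRN+c)/(n_MRN+n_DRN+2c) in [0, 1].
    """
    if form == "log_ratio":
        return _log_ratio(n_mrn, n_drn, pseudocount, "count")
    if form == "fraction":
        if not pseudocount > 0:
            raise InvalidInputError(f"count pseudocount must be > 0, got {pseudocount}")
        if n_mrn < 0 or n_drn < 0:
            raise InvalidInputError(f"counts must be non-negative, got {n_mrn}, {n_drn}")
        return LogRatio(
            value=float((n_mrn + pseudocount) / (n_mrn + n_drn + 2 * pseudocount)),
            pseudocount=float(pseudocount),
        )
    raise InvalidInputError(f"unknown infection-ratio form {form!r}")


@dataclass
class AssociationResult:
    """Pearson association between infection and abundance ratios."""

    r: float
    p: float
    n: int
    infection: np.ndarray
    abundance: np.ndarray
    table: pd.DataFrame


def _summaries_to_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return pd.DataFrame(
        [
            {
                "animal": s.animal,
                "injection_target": s.injection_target,
                "n_drn": s.n_drn,
                "n_mrn": s.n_mrn,
                "d_gl": s.d_gl,
                "d_gcl": s.d_gcl,
            }
            for s in summaries
        ]
    )


def correlate(
    summaries,
    count_pseudocount: float = DEFAULT_COUNT_PSEUDOCOUNT,
    density_pseudocount: float = DEFAULT_DENSITY_PSEUDOCOUNT,
    infection_form: str = "log_ratio",
) -> AssociationResult:
    """Pearson r (with two-sided p) between the two ratios across animals.

    ``summaries`` is an iterable of :class:`AnimalSummary` or a DataFrame
    with columns ``n_drn, n_mrn, d_gl, d_gcl`` (plus optional ``animal``,
    ``injection_target``). Needs n >= 3 and non-constant variates.
    """
    df = _summaries_to_frame(summaries).copy()
    n = len(df)
    if n < 3:
        raise DegreesOfFreedomError(f"correlate needs at least 3 animals, got {n}")
    infection = np.array(
        [
            infection_ratio(row.n_mrn, row.n_drn, count_pseudocount, form=infection_form).value
            for row in df.itertuples()
        ]
    )
    abundance = np.array(
        [
            abundance_ratio(row.d_gl, row.d_gcl, density_pseudocount).value
            for row in df.itertuples()
        ]
    )
    if np.ptp(infection) == 0 or np.ptp(abundance) == 0:
        raise UndefinedCorrelationError("a variate is constant across animals")
    r, p = stats.pearsonr(infection, abundance)
    df["infection_ratio"] = infection
    df["abundance_ratio"] = abundance
    return AssociationResult(r=float(r), p=float(p), n=n, infection=infection, abundance=abundance, table=df)


def abundance_rgb(abundance: LogRatio | float) -> tuple[float, float, float]:
    """Scatter-point colour for an abundance log-ratio.

    The ratio is clipped to [0, 1] and mapped to
    ``(L, 0.8·(1−L), 1−L)``: L = 0 → (0, 0.8, 1), L = 1 → (1, 0, 0).
    """
    value = abundance.value if isinstance(abundance, LogRatio) else float(abundance)
    L = float(np.clip(value, 0.0, 1.0))
    return (L, 0.8 * (1.0 - L), 1.0 - L)
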