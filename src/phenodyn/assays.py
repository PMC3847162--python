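"""Plating-assay statistics.

The fraction of adapted cells at one time point is estimated from replica
plate counts as the mean number of colonies per selective (glucose, no
histidine) plate divided by the mean colony-forming-unit count on rich
(YPD) plates. The ratio is deliberately not clipped at 1: because the two
plate types are independent samples, the estimator can exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedDenominatorError

__all__ = ["PlateCountRecord", "AdaptedFraction", "fraction_adapted"]


@dataclass(frozen=True)
class PlateCountRecord:
    """Colony counts on selective vs rich plates at one time point."""

    time_label: str
    glucose_counts: np.ndarray
    ypd_counts: np.ndarray
    cells_plated: int

    def __post_init__(self) -> None:
        glu = np.atleast_1d(np.asarray(self.glucose_counts))
        ypd = np.atleast_1d(np.asarray(self.ypd_counts))
        if glu.size < 1 or ypd.size < 1:
            raise ValueError("need at least one plate of each type")
        if np.any(glu < 0) or np.any(ypd < 0):
            raise ValueError("plate counts must be non-negative")
        object.__setattr__(self, "glucose_counts", glu)
        object.__setattr__(self, "ypd_counts", ypd)


@dataclass(frozen=True)
class AdaptedFraction:
    """Fraction-adapted estimate with its Poisson-propagated standard error."""

    value: float
    se: float
    time_label: str = ""


def fraction_adapted(record: PlateCountRecord) -> AdaptedFraction:
    """Mean glucose-plate count over mean YPD-plate count.

    Uncertainty assumes independent Poisson counts on each plate, so the
    relative variance of each plate-type mean is 1/(n_plates · mean count)
    and the ratio's relative SE adds them in quadrature. Values above 1 are
    returned as-is.

    Raises
    ------
    UndefinedDenominatorError
        If the YPD plates carry no colonies.
    """
    glu_mean = float(np.mean(record.glucose_counts))
    ypd_mean = float(np.mean(record.ypd_counts))
    if ypd_mean == 0:
        raise UndefinedDenominatorError("mean YPD count is zero; fraction adapted undefined")
    value = glu_mean / ypd_mean
    rel_var = 1.0 / (record.ypd_counts.size * ypd_mean)
    if glu_mean > 0:
        rel_var += 1.0 / (record.glucose_counts.size * glu_mean)
        se = value * float(np.sqrt(rel_var))
    else:
        # zero glucose counts: SE from the Poisson error on the numerator alone
        se = float(np.sqrt(1.0 / record.glucose_counts.size) / ypd_mean)
    return AdaptedFraction(value=value, se=se, time_label=record.time_label)
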