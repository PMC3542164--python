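"""Container for one indicator's observations.

An :class:`IndicatorSample` holds the numeric values reported for a single
quality indicator (one value per reporting unit), optionally together with
the unit identifiers and, for simulated data, boolean truth labels marking
planted outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class IndicatorSample:
    """Observations for one indicator.

    Parameters
    ----------
    values
        Numeric observations. Must be finite; missing values are expected to
        be filtered out at ingest.
    unit_ids
        Optional identifiers of the reporting units, parallel to ``values``.
    truth_labels
        Optional booleans parallel to ``values``; ``True`` marks an
        observation that was planted as a known outlier.
    """

    values: np.ndarray
    unit_ids: np.ndarray | None = None
    truth_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("values must be finite (filter missing values at ingest)")
        object.__setattr__(self, "values", values)
        if self.unit_ids is not None:
            unit_ids = np.asarray(self.unit_ids)
            if unit_ids.shape != values.shape:
                raise ValueError("unit_ids must be parallel to values")
            object.__setattr__(self, "unit_ids", unit_ids)
        if self.truth_labels is not None:
            labels = np.asarray(self.truth_labels, dtype=bool)
            if labels.shape != values.shape:
                raise ValueError("truth_labels must be parallel to values")
            object.__setattr__(self, "truth_labels", labels)

    def __len__(self) -> int:
        return int(self.values.size)
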