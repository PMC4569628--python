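"""The in-memory container for one batch-culture time series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import NDArray

__all__ = ["TimeSeriesDataset"]


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Measurements of one culture condition over a batch run.

    Attributes
    ----------
    times : ndarray
        Sampling times, strictly increasing (hours unless declared
        otherwise via ``time_unit``).
    biomass : ndarray
        Biomass concentration (g/L) at each time, nonnegative.
    product : ndarray or None
        Lipid/product concentration (g/L); optional for growth-only fits.
    condition_label : str
        Free-text condition name, e.g. ``"C. salina N+"``.
    provenance : str
        ``"observed"`` or ``"synthetic"``.
    time_unit : str
        Label for the time axis; must be consistent with the rate
        constant's unit, never converted.
    config : Any
        For synthetic data, the generating configuration (round-trip
        bookkeeping); None for observed data.
    """

    times: NDArray[np.float64]
    biomass: NDArray[np.float64]
    product: NDArray[np.float64] | None = None
    condition_label: str = ""
    provenance: str = "observed"
    time_unit: str = "h"
    config: Any = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.biomass, dtype=float)
        if t.ndim != 1 or x.shape != t.shape:
            raise ValueError("times and biomass must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"times must be strictly increasing (row {bad})")
        if np.any(x < 0):
            raise ValueError("biomass concentrations must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "biomass", x)
        if self.product is not None:
            p = np.asarray(self.product, dtype=float)
            if p.shape != t.shape:
                raise ValueError("product must match times in length")
            if np.any(p < 0):
                raise ValueError("product concentrations must be nonnegative")
            object.__setattr__(self, "product", p)
        if self.provenance not in ("observed", "synthetic"):
            raise ValueError("provenance must be 'observed' or 'synthetic'")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def has_product(self) -> bool:
        return self.product is not None
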