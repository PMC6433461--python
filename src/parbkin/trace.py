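"""Time-resolved intensity traces.

An :class:`IntensityTrace` is the central in-memory record of this package:
the background-corrected integrated fluorescence (in camera counts) of one
DNA molecule's region of interest, sampled at the camera frame rate.
Values may be negative after background correction; times are uniformly
spaced at ``1 / frame_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IntensityTrace"]


@dataclass
class IntensityTrace:
    """Background-corrected intensity versus time for one molecule.

    Parameters
    ----------
    times
        Frame timestamps in seconds, uniformly spaced at ``1/frame_rate``.
    values
        Integrated intensity per frame, in camera counts. May be negative
        after background subtraction.
    frame_rate
        Acquisition rate in Hz.
    molecule_id
        Free-form identifier used in output tables.
    """

    times: np.ndarray
    values: np.ndarray
    frame_rate: float
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-4, atol=2e-6):
                raise ValueError("times must be uniformly spaced at 1/frame_rate")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Span from first to last timestamp, in seconds."""
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    def crop(self, start: float, end: float) -> "IntensityTrace":
        """Return the sub-trace with ``start <= t < end`` (absolute times kept)."""
        mask = (self.times >= start) & (self.times < end)
        return replace(self, times=self.times[mask], values=self.values[mask])

    # ---- I/O: CSV with header `time_s,intensity_counts` -------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the trace as a two-column CSV (``time_s,intensity_counts``)."""
        df = pd.DataFrame({"time_s": self.times, "intensity_counts": self.values})
        df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path, molecule_id: str | None = None) -> "IntensityTrace":
        """Read a trace written by :meth:`to_csv`.

        The frame rate is inferred from the median timestamp spacing.
        """
        df = pd.read_csv(path)
        if not {"time_s", "intensity_counts"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns time_s,intensity_counts")
        times = df["time_s"].to_numpy(float)
        if times.size < 2:
            raise ValueError(f"{path}: need at least 2 samples to infer frame rate")
        frame_rate = 1.0 / float(np.median(np.diff(times)))
        if molecule_id is None:
            molecule_id = Path(path).stem
        return cls(times=times, values=df["intensity_counts"].to_numpy(float),
                   frame_rate=frame_rate, molecule_id=molecule_id)
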