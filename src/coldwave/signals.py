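"""Uniformly sampled waveforms and their on-disk representation.

A :class:`SampledSignal` is the common currency of the pipeline: contact PPG
records, raw iPPG ROI traces, resampled iPPG and filtered signals all travel
in this container.  On disk a signal is a single-column CSV plus a YAML
sidecar carrying the sampling rate, time origin and site metadata, so that
exported synthetic studies can be re-ingested byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = ["SampledSignal", "write_signal", "read_signal"]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled waveform.

    Parameters
    ----------
    values : ndarray
        Sample values, one per time step.
    fs : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds.
    meta : dict
        Free-form metadata (site label, kind, t_cpt, ...).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("signal values must be one-dimensional")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n samples at fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def slice_time(self, start: float, duration: float) -> "SampledSignal":
        """Extract the sub-signal covering ``[start, start + duration)``.

        Raises
        ------
        ValueError
            if the requested window is empty or not fully inside the record.
        """
        if duration <= 0:
            raise ValueError("window duration must be positive")
        i0 = int(round((start - self.t0) * self.fs))
        n_win = int(round(duration * self.fs))
        if i0 < 0 or i0 + n_win > self.n:
            raise ValueError(
                f"window [{start}, {start + duration}) s outside record "
                f"[{self.t0}, {self.t0 + self.duration}) s"
            )
        return replace(self, values=self.values[i0 : i0 + n_win], t0=start)

    def with_values(self, values: np.ndarray) -> "SampledSignal":
        return replace(self, values=np.asarray(values, dtype=float))


def write_signal(signal: SampledSignal, path: Path | str) -> None:
    """Write a signal as ``<path>.csv`` plus a ``<path>.yaml`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path.with_suffix(".csv"), signal.values, fmt="%.17g")
    sidecar = {"fs": float(signal.fs), "t0": float(signal.t0),
               "meta": dict(signal.meta)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_signal(path: Path | str) -> SampledSignal:
    """Read a signal written by :func:`write_signal`."""
    path = Path(path)
    values = np.loadtxt(path.with_suffix(".csv"), dtype=float, ndmin=1)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return SampledSignal(values=values, fs=float(sidecar["fs"]),
                         t0=float(sidecar.get("t0", 0.0)),
                         meta=dict(sidecar.get("meta", {})))
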