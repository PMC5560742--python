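"""In-memory containers shared by every pipeline stage.

The central object is :class:`SensorEpochs`, a trials x channels x samples
array of sensor amplitudes (tesla) with a millisecond time axis and a
per-epoch metadata table.  It is deliberately minimal: the scientific
content of the pipeline is format-agnostic, so a plain array container plus
a :class:`pandas.DataFrame` of event metadata is all that is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Stimulus categories in canonical order: face, banana (natural item), chair
#: (manufactured object).  This order is used for tie-breaking and for the
#: state ordering of transition matrices.
CATEGORIES: tuple[str, ...] = ("F", "B", "C")

#: Null / no-replay label assigned to low-confidence decoded bins.
NULL_LABEL: str = "N"

#: All decoded states, categories first, null last.
STATES: tuple[str, ...] = CATEGORIES + (NULL_LABEL,)

PERSPECTIVES: tuple[str, ...] = ("left60", "front", "right60")

#: Decoding time-bin width (ms).
BIN_MS: float = 20.0

#: Retention analysis window, ms after the offset of the last stimulus
#: (half-open).  Excludes the first second of offset-evoked activity.
RETENTION_WINDOW_MS: tuple[float, float] = (1000.0, 4000.0)

#: Control window, ms relative to the onset of the first stimulus (half-open):
#: the 3000 ms of inter-trial fixation preceding it.
ITI_WINDOW_MS: tuple[float, float] = (-3000.0, 0.0)

#: Alignment events a SensorEpochs time axis may refer to.
ALIGNMENTS: tuple[str, ...] = (
    "stimulus_onset",
    "last_stimulus_offset",
    "first_stimulus_onset",
)


class ValidationError(ValueError):
    """Raised when a container or parameter violates its invariants."""


@dataclass
class SensorEpochs:
    """Epoched multichannel sensor data.

    Parameters
    ----------
    data:
        Array of shape ``(n_epochs, n_channels, n_samples)``, amplitudes in
        tesla.
    time_ms:
        Per-sample time axis in milliseconds relative to ``alignment``,
        strictly increasing with step ``1000 / fs``.
    fs:
        Sampling rate in Hz.
    alignment:
        Which event time 0 refers to; one of :data:`ALIGNMENTS`.
    events:
        One row per epoch.  Always carries ``trial_id``; encoding epochs add
        ``position`` (1-3), ``category``, ``perspective`` and ``is_pm``.
    channel_ids:
        Channel labels, length ``n_channels``.
    """

    data: np.ndarray
    time_ms: np.ndarray
    fs: float
    alignment: str
    events: pd.DataFrame
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (epochs, channels, samples), got {self.data.ndim}-D"
            )
        if self.data.shape[2] != self.time_ms.size:
            raise ValidationError(
                f"time axis length {self.time_ms.size} != sample dimension "
                f"{self.data.shape[2]}"
            )
        if len(self.events) != self.data.shape[0]:
            raise ValidationError(
                f"events has {len(self.events)} rows but data has "
                f"{self.data.shape[0]} epochs"
            )
        if self.alignment not in ALIGNMENTS:
            raise ValidationError(f"unknown alignment {self.alignment!r}")
        if not self.channel_ids:
            self.channel_ids = [f"CH{i:03d}" for i in range(self.data.shape[1])]
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValidationError("channel_ids length != channel dimension")
        step = 1000.0 / self.fs
        if self.time_ms.size > 1:
            dt = np.diff(self.time_ms)
            if not np.allclose(dt, step, rtol=0, atol=1e-6):
                raise ValidationError("time axis step inconsistent with fs")

    # -- convenience -----------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def sample_index(self, t_ms: float, tol: float = 1e-6) -> int:
        """Index of the sample at time ``t_ms`` (must lie on the grid)."""
        idx = int(np.argmin(np.abs(self.time_ms - t_ms)))
        if abs(self.time_ms[idx] - t_ms) > max(tol, 1e-9 * abs(t_ms)):
            raise ValidationError(f"time {t_ms} ms not on the sample grid")
        return idx

    def copy_with(self, **kwargs) -> "SensorEpochs":
        """Shallow-copying replace; events copied to keep alignment safe."""
        out = replace(self, **kwargs)
        out.events = out.events.reset_index(drop=True)
        return out


def time_axis(t_start_ms: float, n_samples: int, fs: float) -> np.ndarray:
    """Uniform time axis starting at ``t_start_ms`` with ``n_samples`` points."""
    return t_start_ms + np.arange(n_samples) * (1000.0 / fs)
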