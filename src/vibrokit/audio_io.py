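"""Reading, chunking and annotating long contact-microphone recordings.

Recordings are uncompressed PCM WAV files (48 kHz in the field protocol this
package targets). Amplitudes are treated as proportional to millivolts; no
absolute calibration is attempted, because every downstream threshold is
scale-relative. Long recordings are split into fixed-length chunks (10 min by
default) so that noise profiling and detection can adapt to local background
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "RecordingChunk",
    "DeploymentMap",
    "TemperatureSeries",
    "read_wav",
    "write_wav",
    "chunk_recording",
    "load_deployment_metadata",
    "temperature_at",
]

#: Substrate categories recognised in deployment metadata.
SUBSTRATES = ("leaf_litter", "pine_litter")


class AudioFormatError(ValueError):
    """Raised for unreadable, compressed or multi-channel audio input."""


@dataclass
class Waveform:
    """A mono amplitude sequence with sample rate and absolute start time.

    ``samples`` are signed floats on a scale proportional to mV.
    """

    samples: np.ndarray
    sample_rate: int = 48000
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioFormatError("waveform must be mono (1-D samples)")
        if self.samples.size == 0:
            raise ValueError("waveform must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class RecordingChunk:
    """A contiguous segment of a recording with its deployment identity."""

    waveform: Waveform
    unit_id: str = "unit"
    plot_id: str = "plot"
    substrate: str = "leaf_litter"
    chunk_index: int = 0


@dataclass
class DeploymentMap:
    """Maps recording units to plots, substrates and positions."""

    unit_to_plot: dict[str, str]
    unit_to_substrate: dict[str, str]
    unit_to_position: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def plot_to_substrate(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for unit, plot in self.unit_to_plot.items():
            out[plot] = self.unit_to_substrate[unit]
        return out

    def __len__(self) -> int:
        return len(self.unit_to_plot)


@dataclass
class TemperatureSeries:
    """(datetime, °C) readings for one plot at nominal 15-min spacing."""

    times: list[datetime]
    temps_c: list[float]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.temps_c):
            raise ValueError("times and temps_c must have equal length")
        if len(self.times) == 0:
            raise ValueError("temperature series is empty")
        for a, b in zip(self.times, self.times[1:]):
            if b <= a:
                raise ValueError("timestamps must be strictly increasing")


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file into a :class:`Waveform`.

    Integer PCM samples are returned as floats with their original integer
    values (no normalisation), so a file written by :func:`write_wav`
    round-trips bit-exactly. Multi-channel files are rejected.
    """
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, OSError) as exc:
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise AudioFormatError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    return Waveform(samples=data.astype(np.float64), sample_rate=int(rate))


def write_wav(path: str | Path, waveform: Waveform) -> None:
    """Write a waveform as 16-bit PCM. Samples are clipped to int16 range."""
    clipped = np.clip(np.round(waveform.samples), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(waveform.sample_rate), clipped)


def chunk_recording(
    waveform: Waveform,
    chunk_seconds: float = 600.0,
    unit_id: str = "unit",
    plot_id: str = "plot",
    substrate: str = "leaf_litter",
) -> list[RecordingChunk]:
    """Split a recording into contiguous chunks of ``chunk_seconds``.

    The concatenation of chunk samples equals the input samples exactly; all
    chunks have the requested duration except possibly the last.
    """
    if chunk_seconds <= 0:
        raise ValueError("chunk_seconds must be positive")
    n_per = int(round(chunk_seconds * waveform.sample_rate))
    chunks: list[RecordingChunk] = []
    for index, start in enumerate(range(0, waveform.samples.size, n_per)):
        seg = waveform.samples[start : start + n_per]
        t0 = waveform.start_time
        if t0 is not None:
            t0 = t0 + timedelta(seconds=start / waveform.sample_rate)
        chunks.append(
            RecordingChunk(
                waveform=Waveform(seg, waveform.sample_rate, t0),
                unit_id=unit_id,
                plot_id=plot_id,
                substrate=substrate,
                chunk_index=index,
            )
        )
    return chunks


def load_deployment_metadata(path: str | Path) -> DeploymentMap:
    """Load and validate a deployment table (CSV: unit_id,plot_id,substrate)."""
    df = pd.read_csv(path, dtype=str)
    required = {"unit_id", "plot_id", "substrate"}
    if df.empty:
        raise ValueError(f"{path}: deployment table is empty")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["unit_id"].duplicated().any():
        dupes = df.loc[df["unit_id"].duplicated(), "unit_id"].tolist()
        raise ValueError(f"{path}: duplicate unit_id entries {dupes}")
    bad = set(df["substrate"]) - set(SUBSTRATES)
    if bad:
        raise ValueError(
            f"{path}: unknown substrate values {sorted(bad)}; "
            f"expected one of {SUBSTRATES}"
        )
    unit_to_plot = dict(zip(df["unit_id"], df["plot_id"]))
    unit_to_substrate = dict(zip(df["unit_id"], df["substrate"]))
    position: dict[str, tuple[float, float]] = {}
    if {"x", "y"} <= set(df.columns):
        for _, row in df.iterrows():
            position[row["unit_id"]] = (float(row["x"]), float(row["y"]))
    return DeploymentMap(unit_to_plot, unit_to_substrate, position)


def temperature_at(series: TemperatureSeries, t: datetime) -> float:
    """Temperature at the reading nearest to ``t`` (ties -> earlier reading).

    ``t`` must lie within the series range padded by 15 min on each side.
    """
    pad = timedelta(minutes=15)
    if t < series.times[0] - pad or t > series.times[-1] + pad:
        raise ValueError(
            f"{t} outside temperature series range "
            f"[{series.times[0]}, {series.times[-1]}] ± 15 min"
        )
    best_i = 0
    best_d = abs((t - series.times[0]).total_seconds())
    for i, ti in enumerate(series.times[1:], start=1):
        d = abs((t - ti).total_seconds())
        if d < best_d:  # strict: ties keep the earlier reading
            best_d, best_i = d, i
    return series.temps_c[best_i]
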