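"""Interaction-window predictors for signal-interference analysis.

For each focal signal bout, every other event recorded at the same unit
within ±15 min ("interaction time window") is a potential interferer. This
module computes, per focal bout:

* noise abundance — the count of co-occurring events of any other type
  (abiotic, biotic, airborne or substrate-borne);
* noise diversity — the Shannon entropy of co-occurring type proportions,
  normalised by the maximum entropy log(n) so it lies in [0, 1];
* conspecific / heterospecific counts and their relative abundances (count
  divided by the dataset-wide maximum count for that signal class);

and assembles regression-ready tables (response, predictors, interaction
term, temperature covariate). Fitting the mixed-effects models themselves is
left to standard statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import TemperatureSeries, temperature_at

__all__ = [
    "InteractionWindowSummary",
    "interaction_window",
    "shannon_diversity",
    "noise_abundance",
    "relative_abundance",
    "summarize_windows",
    "build_model_table",
]

HALF_WIDTH_S = 900.0  # ±15 min


@dataclass
class InteractionWindowSummary:
    """Counts and diversity of events around one focal bout."""

    focal_bout_id: object
    noise_abundance: int
    n_types: int
    diversity: float
    conspecific_count: int
    heterospecific_count: int


def interaction_window(
    focal: pd.Series,
    events: pd.DataFrame,
    half_width: float = HALF_WIDTH_S,
) -> pd.DataFrame:
    """Events at the focal bout's unit starting within ±``half_width`` s.

    The window is anchored to [focal start − half_width, focal end +
    half_width], boundaries inclusive; the focal bout itself is excluded.
    Membership is judged by an event's start time.
    """
    if events.empty:
        return events
    start = pd.to_datetime(events["start_time"])
    f_start = pd.Timestamp(focal["start_time"])
    f_end = pd.Timestamp(focal.get("end_time", focal["start_time"]))
    lo = f_start - pd.Timedelta(seconds=half_width)
    hi = f_end + pd.Timedelta(seconds=half_width)
    mask = (
        (events["unit_id"] == focal["unit_id"])
        & (start >= lo)
        & (start <= hi)
        & (events["bout_id"] != focal["bout_id"])
    )
    return events[mask]


def shannon_diversity(window_events: pd.DataFrame) -> float:
    """Normalised Shannon entropy of event-type proportions in a window.

    H = −Σ p_i ln p_i over type proportions, divided by ln(n) for n ≥ 2
    distinct types; 0 when the window holds at most one type. Equals 1 iff
    the counts are uniform over ≥ 2 types.
    """
    if window_events.empty:
        return 0.0
    counts = window_events["type_label"].value_counts().to_numpy(dtype=np.float64)
    n = counts.size
    if n <= 1:
        return 0.0
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(n)


def noise_abundance(window_events: pd.DataFrame, focal_type: str) -> int:
    """Count of window events of any type other than the focal type."""
    if window_events.empty:
        return 0
    return int((window_events["type_label"] != focal_type).sum())


def relative_abundance(count: int, max_count: int) -> float:
    """Count scaled by the dataset-wide maximum count of that signal class."""
    if max_count <= 0:
        raise ValueError("signal class never observed (max_count = 0)")
    return count / max_count


def summarize_windows(
    events: pd.DataFrame,
    focal_type: str,
    heterospecific_type: str | None = None,
    half_width: float = HALF_WIDTH_S,
) -> pd.DataFrame:
    """One row of window predictors per focal bout of ``focal_type``.

    Columns: bout_id, noise_abundance, n_types, diversity, conspecific_count,
    heterospecific_count, plus relative abundances scaled by the maxima over
    all windows of the focal species (so each relative abundance attains 1
    somewhere in the dataset).
    """
    focals = events[events["type_label"] == focal_type]
    rows = []
    for _, focal in focals.iterrows():
        win = interaction_window(focal, events, half_width)
        het = 0
        if heterospecific_type is not None:
            het = int((win["type_label"] == heterospecific_type).sum()) if not win.empty else 0
        rows.append({
            "bout_id": focal["bout_id"],
            "noise_abundance": noise_abundance(win, focal_type),
            "n_types": int(win["type_label"].nunique()) if not win.empty else 0,
            "diversity": shannon_diversity(win),
            "conspecific_count": int((win["type_label"] == focal_type).sum())
                                 if not win.empty else 0,
            "heterospecific_count": het,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for col in ("conspecific_count", "heterospecific_count"):
        mx = int(out[col].max())
        out[col.replace("_count", "_relative")] = (
            out[col] / mx if mx > 0 else 0.0
        )
    return out


def build_model_table(
    events: pd.DataFrame,
    focal_type: str,
    temperature: TemperatureSeries | dict[str, TemperatureSeries],
    response: str = "duration_s",
    heterospecific_type: str | None = None,
    half_width: float = HALF_WIDTH_S,
) -> pd.DataFrame:
    """Regression-ready table: one row per focal bout.

    Columns: the response, noise abundance, diversity, their product
    (interaction term), conspecific/heterospecific relative abundances and
    their product, and the temperature nearest the bout start (the random
    effect). Rows whose response is missing, or whose plot lacks temperature
    coverage, are dropped.

    ``temperature`` is one series or a mapping plot_id -> series.
    """
    windows = summarize_windows(events, focal_type, heterospecific_type,
                                half_width)
    focals = events[events["type_label"] == focal_type].set_index("bout_id")
    rows = []
    for _, w in windows.iterrows():
        focal = focals.loc[w["bout_id"]]
        resp = focal.get(response, np.nan)
        if pd.isna(resp):
            continue
        series = temperature
        if isinstance(temperature, dict):
            series = temperature.get(focal["plot_id"])
            if series is None:
                continue
        try:
            temp = temperature_at(series, pd.Timestamp(focal["start_time"]).to_pydatetime())
        except ValueError:
            continue  # no temperature coverage for this bout
        het_rel = w.get("heterospecific_relative", 0.0)
        rows.append({
            "bout_id": w["bout_id"],
            "response": response,
            "value": float(resp),
            "noise_abundance": w["noise_abundance"],
            "diversity": w["diversity"],
            "noise_x_diversity": w["noise_abundance"] * w["diversity"],
            "conspecific_relative": w.get("conspecific_relative", 0.0),
            "heterospecific_relative": het_rel,
            "conspecific_x_heterospecific":
                w.get("conspecific_relative", 0.0) * het_rel,
            "temperature_c": temp,
        })
    return pd.DataFrame(rows)
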