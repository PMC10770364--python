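"""Pulse detection, bout segmentation and event-catalog rules.

Pulses are local maxima of the rectified denoised signal above an updated
sigma-clipping threshold (the threshold multiplier is re-selected on the
denoised chunk, since denoising changes the amplitude statistics). Pulses
are grouped into bouts by a 3-component Gaussian mixture fitted to the
log10 of inter-pulse intervals: the three components correspond to
within-bout intervals, between-bout intervals inside one signaling activity,
and intervals between signaling activities, whose time scales span several
orders of magnitude (hence the log scale). A new bout starts wherever an
interval's maximum-posterior component is not the within-bout one.

Catalog-level rules then mirror the field protocol: consecutive same-type
bouts at the same sensor within one minute are merged; same-type bouts
registered simultaneously by multiple sensors of one plot are collapsed to a
single bout flagged as airborne (an air-transmitted sound reaching the
ground); types observed 100 times or fewer are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

from .audio_io import RecordingChunk
from .denoise import AlphaScan, select_alpha

__all__ = [
    "Pulse",
    "PulseDetection",
    "IntervalModel",
    "Bout",
    "InsufficientIntervals",
    "COMPONENT_LABELS",
    "detect_pulses",
    "fit_interval_model",
    "group_pulses",
    "group_pulses_fallback",
    "segment_chunk",
    "bouts_to_catalog",
    "merge_same_sensor",
    "resolve_airborne",
    "filter_rare_types",
    "apply_labels",
]

COMPONENT_LABELS = ("within_bout", "between_bout", "between_activity")

MIN_INTERVALS_FOR_GMM = 10


class InsufficientIntervals(ValueError):
    """Too few inter-pulse intervals for a mixture fit; use fallback grouping."""


@dataclass(frozen=True)
class Pulse:
    """One detected pulse: time from chunk start (s) and amplitude (mV)."""

    time: float
    amplitude: float


@dataclass
class PulseDetection:
    """Detected pulses plus the threshold scan that produced them."""

    pulses: list[Pulse]
    scan: AlphaScan


@dataclass
class IntervalModel:
    """3-component Gaussian mixture over log10 inter-pulse intervals.

    Components are labelled within_bout / between_bout / between_activity in
    ascending order of mean interval; ties break by weight (the heavier
    component is the faster scale, since within-bout intervals dominate).
    """

    means: np.ndarray        # log10 seconds, ascending
    variances: np.ndarray
    weights: np.ndarray
    _gmm: GaussianMixture = field(repr=False)
    _order: np.ndarray = field(repr=False)

    def classify(self, intervals: np.ndarray) -> np.ndarray:
        """Maximum-posterior component label for each interval (seconds)."""
        logt = np.log10(np.asarray(intervals, dtype=np.float64)).reshape(-1, 1)
        raw = self._gmm.predict(logt)
        rank = np.empty_like(self._order)
        rank[self._order] = np.arange(3)
        return np.array([COMPONENT_LABELS[rank[c]] for c in raw])


@dataclass
class Bout:
    """A group of pulses produced as one continuous signaling unit."""

    pulses: list[Pulse]
    unit_id: str = "unit"
    plot_id: str = "plot"
    substrate: str = "leaf_litter"
    type_label: str = "unknown"
    airborne: bool = False
    chunk_start_time: datetime | None = None

    @property
    def start_s(self) -> float:
        return self.pulses[0].time

    @property
    def end_s(self) -> float:
        return self.pulses[-1].time

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    @property
    def start_time(self) -> datetime | float:
        if self.chunk_start_time is None:
            return self.start_s
        return self.chunk_start_time + timedelta(seconds=self.start_s)

    @property
    def end_time(self) -> datetime | float:
        if self.chunk_start_time is None:
            return self.end_s
        return self.chunk_start_time + timedelta(seconds=self.end_s)


def detect_pulses(
    chunk: RecordingChunk,
    min_separation: float = 0.04,
    alphas: np.ndarray | None = None,
) -> PulseDetection:
    """Detect pulses in a (denoised) chunk.

    Re-selects the threshold multiplier on this chunk's samples, then takes
    local maxima of ``|x|`` above the threshold with a minimum peak
    separation (default 40 ms — above the ring-down of impulsive pulses,
    below typical within-bout pulse rates).
    """
    w = chunk.waveform
    x = np.abs(w.samples)
    scan = select_alpha(w.samples, alphas)
    T = scan.threshold.T
    if T <= 0 or not (x > T).any():
        return PulseDetection(pulses=[], scan=scan)
    distance = max(1, int(round(min_separation * w.sample_rate)))
    peaks, props = find_peaks(x, height=T, distance=distance)
    pulses = [Pulse(time=p / w.sample_rate, amplitude=float(x[p])) for p in peaks]
    return PulseDetection(pulses=pulses, scan=scan)


def fit_interval_model(intervals: np.ndarray, seed: int = 0) -> IntervalModel:
    """Fit the 3-Gaussian mixture to log10 inter-pulse intervals.

    Deterministic given ``seed`` (k-means initialisation, 5 restarts, best
    likelihood kept). Raises :class:`InsufficientIntervals` below 10
    intervals.
    """
    iv = np.asarray(intervals, dtype=np.float64)
    if iv.size < MIN_INTERVALS_FOR_GMM:
        raise InsufficientIntervals(
            f"{iv.size} intervals < {MIN_INTERVALS_FOR_GMM}; use fallback grouping"
        )
    if (iv <= 0).any():
        raise ValueError("intervals must be positive")
    logt = np.log10(iv).reshape(-1, 1)
    gmm = GaussianMixture(
        n_components=3,
        covariance_type="full",
        n_init=5,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-6,
    ).fit(logt)
    means = gmm.means_.ravel()
    weights = gmm.weights_.ravel()
    # ascending mean; exact ties broken by descending weight
    order = np.lexsort((-weights, means))
    return IntervalModel(
        means=means[order],
        variances=gmm.covariances_.reshape(3)[order],
        weights=weights[order],
        _gmm=gmm,
        _order=order,
    )


def _new_bout(template: RecordingChunk | None, pulses: list[Pulse]) -> Bout:
    if template is None:
        return Bout(pulses=pulses)
    return Bout(
        pulses=pulses,
        unit_id=template.unit_id,
        plot_id=template.plot_id,
        substrate=template.substrate,
        chunk_start_time=template.waveform.start_time,
    )


def group_pulses(
    pulses: list[Pulse],
    model: IntervalModel,
    chunk: RecordingChunk | None = None,
) -> list[Bout]:
    """Group time-ordered pulses into bouts by interval classification.

    A new bout starts at every interval whose maximum-posterior component is
    between_bout or between_activity. A single pulse forms a zero-duration
    bout. Every pulse belongs to exactly one bout.
    """
    if not pulses:
        return []
    if len(pulses) == 1:
        return [_new_bout(chunk, list(pulses))]
    times = np.array([p.time for p in pulses])
    labels = model.classify(np.diff(times))
    bouts: list[Bout] = []
    current = [pulses[0]]
    for pulse, label in zip(pulses[1:], labels):
        if label == "within_bout":
            current.append(pulse)
        else:
            bouts.append(_new_bout(chunk, current))
            current = [pulse]
    bouts.append(_new_bout(chunk, current))
    return bouts


def group_pulses_fallback(
    pulses: list[Pulse],
    gap: float = 2.0,
    chunk: RecordingChunk | None = None,
) -> list[Bout]:
    """Single-threshold grouping for chunks with too few intervals for a fit:
    a new bout starts wherever the inter-pulse interval exceeds ``gap``."""
    if not pulses:
        return []
    bouts: list[Bout] = []
    current = [pulses[0]]
    for prev, pulse in zip(pulses, pulses[1:]):
        if pulse.time - prev.time <= gap:
            current.append(pulse)
        else:
            bouts.append(_new_bout(chunk, current))
            current = [pulse]
    bouts.append(_new_bout(chunk, current))
    return bouts


def segment_chunk(
    chunk: RecordingChunk,
    seed: int = 0,
    min_separation: float = 0.04,
    fallback_gap: float = 2.0,
) -> tuple[list[Bout], PulseDetection]:
    """Detect pulses and group them into bouts for one chunk.

    Falls back to single-threshold grouping when the chunk yields fewer than
    10 inter-pulse intervals.
    """
    detection = detect_pulses(chunk, min_separation=min_separation)
    pulses = detection.pulses
    intervals = np.diff([p.time for p in pulses]) if len(pulses) > 1 else np.array([])
    try:
        model = fit_interval_model(intervals, seed=seed)
        bouts = group_pulses(pulses, model, chunk)
    except InsufficientIntervals:
        bouts = group_pulses_fallback(pulses, gap=fallback_gap, chunk=chunk)
    return bouts, detection


def bouts_to_catalog(bouts: list[Bout], start_id: int = 0) -> pd.DataFrame:
    """Flatten bouts into the event-catalog table.

    Columns: bout_id, unit_id, plot_id, substrate, start_time, end_time,
    duration_s, dominant_freq_hz, type_label, airborne.
    """
    rows = []
    for i, b in enumerate(bouts, start=start_id):
        rows.append({
            "bout_id": i,
            "unit_id": b.unit_id,
            "plot_id": b.plot_id,
            "substrate": b.substrate,
            "start_time": b.start_time,
            "end_time": b.end_time,
            "duration_s": b.duration,
            "dominant_freq_hz": np.nan,
            "type_label": b.type_label,
            "airborne": b.airborne,
        })
    return pd.DataFrame(rows, columns=[
        "bout_id", "unit_id", "plot_id", "substrate", "start_time",
        "end_time", "duration_s", "dominant_freq_hz", "type_label", "airborne",
    ])


def _seconds(delta) -> float:
    return delta.total_seconds() if hasattr(delta, "total_seconds") else float(delta)


def merge_same_sensor(catalog: pd.DataFrame, merge_window: float = 60.0) -> pd.DataFrame:
    """Merge consecutive same-type bouts at one sensor within ``merge_window``.

    Merging is transitive: a chain of bouts each within 60 s of its
    predecessor collapses to one bout spanning the union of their times. The
    merged row keeps the identity and type of its first member; duration is
    recomputed from the union span.
    """
    if catalog.empty:
        return catalog.copy()
    out = []
    for _, group in catalog.sort_values("start_time").groupby(
        ["unit_id", "type_label"], sort=False
    ):
        rows = group.to_dict("records")
        current = dict(rows[0])
        for row in rows[1:]:
            if _seconds(row["start_time"] - current["end_time"]) <= merge_window:
                current["end_time"] = max(current["end_time"], row["end_time"])
            else:
                out.append(current)
                current = dict(row)
        out.append(current)
    merged = pd.DataFrame(out)
    merged["duration_s"] = [
        _seconds(e - s) for s, e in zip(merged["start_time"], merged["end_time"])
    ]
    return merged.sort_values("start_time").reset_index(drop=True)


def resolve_airborne(catalog: pd.DataFrame, simultaneity_tol: float = 1.0) -> pd.DataFrame:
    """Collapse same-type bouts heard simultaneously on several sensors.

    Within one plot, same-type bouts whose time spans overlap after
    expanding each span by ``simultaneity_tol`` seconds, across at least two
    distinct sensors, are an air-transmitted sound registered plot-wide:
    they collapse to a single bout flagged ``airborne=True`` spanning the
    union of times. Bouts heard on a single sensor stay substrate-borne.
    """
    if catalog.empty:
        return catalog.copy()
    first_start = catalog["start_time"].iloc[0]
    tol = (pd.Timedelta(seconds=simultaneity_tol)
           if isinstance(first_start, (pd.Timestamp, datetime))
           else simultaneity_tol)
    out = []
    for _, group in catalog.sort_values("start_time").groupby(
        ["plot_id", "type_label"], sort=False
    ):
        rows = group.to_dict("records")
        cluster: list[dict] = []
        cluster_end = None

        def flush() -> None:
            if not cluster:
                return
            units = {r["unit_id"] for r in cluster}
            if len(units) >= 2:
                first = dict(min(cluster, key=lambda r: r["start_time"]))
                first["end_time"] = max(r["end_time"] for r in cluster)
                first["duration_s"] = _seconds(first["end_time"] - first["start_time"])
                first["airborne"] = True
                out.append(first)
            else:
                out.extend(cluster)

        for row in rows:
            if cluster and row["start_time"] - tol <= cluster_end + tol:
                cluster.append(row)
                cluster_end = max(cluster_end, row["end_time"])
            else:
                flush()
                cluster = [row]
                cluster_end = row["end_time"]
        flush()
    return pd.DataFrame(out).sort_values("start_time").reset_index(drop=True)


def filter_rare_types(catalog: pd.DataFrame, min_count: int = 100) -> pd.DataFrame:
    """Keep only types observed strictly more than ``min_count`` times."""
    if catalog.empty:
        return catalog.copy()
    counts = catalog["type_label"].value_counts()
    keep = counts[counts > min_count].index
    return catalog[catalog["type_label"].isin(keep)].reset_index(drop=True)


def apply_labels(catalog: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Attach expert type labels (columns bout_id, type_label) to the catalog.

    Bouts without a label keep the label "unknown".
    """
    mapping = dict(zip(labels["bout_id"], labels["type_label"]))
    out = catalog.copy()
    out["type_label"] = [
        mapping.get(b, t if isinstance(t, str) and t else "unknown")
        for b, t in zip(out["bout_id"], out["type_label"])
    ]
    return out
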