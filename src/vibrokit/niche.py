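"""Acoustic-niche distributions and Pianka overlap indices.

Classified signal bouts are binned along four niche dimensions — space
(substrate category or recording plot), date (calendar day), time of day
(96 bins of 15 min) and dominant frequency (10-Hz bins) — and pairwise
species overlap on each dimension is quantified with Pianka's niche overlap
index

    PI_ij = sum_k(P_ik * P_jk) / sqrt(sum_k(P_ik^2) * sum_k(P_jk^2))

where ``P_ik`` is species *i*'s proportion of use of resource bin *k*
(0 = no overlap, 1 = complete overlap). Temporal overlap is the product of
the date and time-of-day indices; overall overlap is the product over all
four dimensions. Airborne-flagged events are excluded: an airborne sound's
spatial and spectral niche is not comparable with substrate-borne signaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NicheDistribution",
    "OverlapResult",
    "DIMENSIONS",
    "bin_events",
    "pianka_index",
    "temporal_overlap",
    "overall_overlap",
    "overlap_matrix",
]

DIMENSIONS = ("space", "date", "time_of_day", "frequency")

#: 15-min time-of-day bins, indexed 0..95 from midnight.
N_TOD_BINS = 96
FREQ_BIN_HZ = 10.0


@dataclass
class NicheDistribution:
    """A proportion vector over the bins of one niche dimension."""

    dimension: str
    bin_labels: list
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=np.float64)
        if len(self.bin_labels) != self.proportions.size:
            raise ValueError("bin_labels and proportions must align")
        if (self.proportions < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        total = self.proportions.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")


@dataclass
class OverlapResult:
    """Pairwise Pianka indices for one species pair."""

    species_a: str
    species_b: str
    by_dimension: dict[str, float]

    @property
    def temporal(self) -> float:
        return temporal_overlap(self.by_dimension["date"],
                                self.by_dimension["time_of_day"])

    @property
    def overall(self) -> float:
        return overall_overlap(
            self.by_dimension["space"],
            self.by_dimension["date"],
            self.by_dimension["time_of_day"],
            self.by_dimension["frequency"],
        )


def _dimension_values(events: pd.DataFrame, dimension: str, space_by: str):
    start = pd.to_datetime(events["start_time"])
    if dimension == "space":
        return events["substrate" if space_by == "substrate" else "plot_id"]
    if dimension == "date":
        return start.dt.date
    if dimension == "time_of_day":
        return (start.dt.hour * 60 + start.dt.minute) // 15
    if dimension == "frequency":
        freq = pd.to_numeric(events["dominant_freq_hz"])
        if freq.isna().any():
            raise ValueError("events with undefined dominant frequency cannot "
                             "enter the frequency niche dimension")
        return (np.floor(freq / FREQ_BIN_HZ) * FREQ_BIN_HZ).astype(float)
    raise ValueError(f"unknown niche dimension {dimension!r}; "
                     f"expected one of {DIMENSIONS}")


def bin_events(
    events: pd.DataFrame,
    dimension: str,
    bin_labels: Sequence | None = None,
    space_by: str = "substrate",
) -> NicheDistribution:
    """Bin an event catalog along one niche dimension into proportions.

    ``bin_labels`` fixes the bin structure (needed for cross-species
    comparison); by default the observed values define it. Time-of-day always
    uses all 96 15-min bins. ``space_by`` selects substrate-category bins
    (default) or per-plot bins.
    """
    if events.empty:
        raise ValueError("cannot bin an empty event catalog")
    values = _dimension_values(events, dimension, space_by)
    if dimension == "time_of_day" and bin_labels is None:
        bin_labels = list(range(N_TOD_BINS))
    if bin_labels is None:
        bin_labels = sorted(pd.unique(values))
    counts = pd.Series(values).value_counts()
    vec = np.array([counts.get(lbl, 0) for lbl in bin_labels], dtype=np.float64)
    if vec.sum() == 0:
        raise ValueError(f"no events fall in the provided {dimension} bins")
    return NicheDistribution(dimension, list(bin_labels), vec / vec.sum())


def pianka_index(p: np.ndarray | NicheDistribution,
                 q: np.ndarray | NicheDistribution) -> float:
    """Pianka's niche overlap index of two proportion vectors.

    Symmetric, in [0, 1]; 1 iff the vectors are proportional (equal, for
    probability vectors) and 0 iff their supports are disjoint.
    """
    if isinstance(p, NicheDistribution):
        p = p.proportions
    if isinstance(q, NicheDistribution):
        q = q.proportions
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("distributions must share one bin structure")
    denom = np.sqrt((p * p).sum() * (q * q).sum())
    if denom == 0:
        raise ValueError("zero distribution has no defined overlap")
    return float(np.clip((p * q).sum() / denom, 0.0, 1.0))


def temporal_overlap(pi_date: float, pi_time_of_day: float) -> float:
    """Temporal overlap: seasonal (date) × diurnal (time-of-day) indices."""
    return pi_date * pi_time_of_day


def overall_overlap(pi_space: float, pi_date: float,
                    pi_time_of_day: float, pi_frequency: float) -> float:
    """Overall acoustic niche overlap: product of the four per-dimension
    indices (space × date × time-of-day × dominant frequency)."""
    return pi_space * pi_date * pi_time_of_day * pi_frequency


def overlap_matrix(
    events: pd.DataFrame,
    species: Sequence[str],
    space_by: str = "substrate",
    include_airborne: bool = False,
) -> list[OverlapResult]:
    """All pairwise per-dimension and overall overlaps among ``species``.

    Bin structures are shared across species (built from the pooled catalog)
    so that proportion vectors are comparable. Airborne-flagged events are
    dropped unless ``include_airborne``.
    """
    if len(species) < 2:
        raise ValueError("need at least two species")
    ev = events
    if not include_airborne and "airborne" in ev.columns:
        ev = ev[~ev["airborne"].astype(bool)]
    pooled_bins = {
        dim: bin_events(ev[ev["type_label"].isin(species)], dim,
                        space_by=space_by).bin_labels
        for dim in DIMENSIONS
    }
    dists: dict[str, dict[str, NicheDistribution]] = {}
    for sp in species:
        sub = ev[ev["type_label"] == sp]
        if sub.empty:
            raise ValueError(f"species {sp!r} has no events in the catalog")
        dists[sp] = {
            dim: bin_events(sub, dim, bin_labels=pooled_bins[dim],
                            space_by=space_by)
            for dim in DIMENSIONS
        }
    out = []
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            by_dim = {dim: pianka_index(dists[a][dim], dists[b][dim])
                      for dim in DIMENSIONS}
            out.append(OverlapResult(a, b, by_dim))
    return out


def overlap_table(results: list[OverlapResult]) -> pd.DataFrame:
    """Tidy table of pairwise overlaps (one row per pair)."""
    rows = []
    for r in results:
        row = {"species_a": r.species_a, "species_b": r.species_b}
        row.update({f"pi_{d}": r.by_dimension[d] for d in DIMENSIONS})
        row["pi_temporal"] = r.temporal
        row["pi_overall"] = r.overall
        rows.append(row)
    return pd.DataFrame(rows)
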