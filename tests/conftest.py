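"""Shared fixtures: small synthetic catalogs and rendered scenes."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from vibrokit import audio_io, denoise, events, scenes


def make_catalog(rows: list[dict]) -> pd.DataFrame:
    """Build an event-catalog frame from partial row dicts."""
    defaults = {
        "unit_id": "A-u01",
        "plot_id": "A",
        "substrate": "leaf_litter",
        "duration_s": 1.0,
        "dominant_freq_hz": 400.0,
        "type_label": "sp1",
        "airborne": False,
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r["bout_id"] = i
        r.update(row)
        if "end_time" not in r:
            r["end_time"] = r["start_time"] + timedelta(seconds=r["duration_s"])
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture
def t0() -> datetime:
    return datetime(2018, 6, 1, 12, 0, 0)


@pytest.fixture(scope="session")
def reference_scene():
    """The 10-min reference detection scene, rendered once per session."""
    spec = scenes.default_scene(seed=1)
    wave, truth = scenes.render_scene(spec)
    return spec, wave, truth


@pytest.fixture(scope="session")
def detected_reference_scene(reference_scene):
    """Denoise + detect + group on the reference scene (expensive; shared)."""
    spec, wave, truth = reference_scene
    chunk = audio_io.RecordingChunk(waveform=wave)
    result = denoise.denoise_chunk(chunk)
    bouts, detection = events.segment_chunk(result.chunk, seed=1)
    return spec, truth, result, bouts, detection


@pytest.fixture(scope="session")
def short_scene():
    """A 2-min scene with dense activity, for mid-weight denoise tests."""
    spec = scenes.SceneSpec(
        duration_s=120.0,
        species=[scenes.SpeciesSpec(
            label="sp", center_freq_hz=400.0, snr_db=15.0, n_bouts=6,
            bouts_per_activity=3, between_activity_s=(20.0, 0.05))],
        seed=5,
    )
    wave, truth, comp = scenes.render_scene(spec, return_components=True)
    return spec, wave, truth, comp


@pytest.fixture
def catalog_spec_identical() -> scenes.CatalogSpec:
    """Two species drawing events from identical niche distributions."""
    days = {date(2018, 6, d): p for d, p in [(1, 0.5), (2, 0.3), (3, 0.2)]}
    tod = np.zeros(96)
    tod[80:92] = 1.0  # active 20:00-23:00
    freqs = {300.0: 0.3, 310.0: 0.4, 320.0: 0.3}
    mk = lambda lbl, n: scenes.SpeciesCatalogSpec(
        label=lbl, n_events=n,
        substrate_probs={"leaf_litter": 0.8, "pine_litter": 0.2},
        date_probs=days, tod_probs=tod.copy(), freq_bin_probs=dict(freqs),
    )
    return scenes.CatalogSpec(species=[mk("spA", 10_000), mk("spB", 10_000)],
                              seed=11)
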