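import numpy as np
import pytest

from patchkit import Track


@pytest.fixture
def make_track():
    """Factory for hand-built tracks with sensible defaults."""

    def _make(
        x,
        y=None,
        intensity=None,
        dt=1.0,
        track_id="t0",
        protein="coat",
        fluorophore="GFP",
    ):
        x = np.asarray(x, dtype=float)
        n = len(x)
        y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
        if intensity is None:
            intensity = np.ones(n)
        return Track(
            track_id=track_id,
            times=np.arange(n) * dt,
            x=x,
            y=y,
            intensity=np.asarray(intensity, dtype=float),
            frame_interval=dt,
            protein=protein,
            fluorophore=fluorophore,
        )

    return _make


@pytest.fixture
def random_track():
    """Factory for random-walk tracks, seeded for reproducibility."""

    def _make(seed=0, n=30, dt=0.5, scale=50.0, track_id=None):
        rng = np.random.default_rng(seed)
        return Track(
            track_id=track_id or f"rand{seed}",
            times=np.arange(n) * dt,
            x=np.cumsum(rng.normal(0, scale, n)),
            y=np.cumsum(rng.normal(0, scale, n)),
            intensity=rng.uniform(0.5, 2.0, n),
            frame_interval=dt,
        )

    return _make
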