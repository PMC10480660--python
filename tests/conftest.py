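import numpy as np
import pytest

from htpaint import sim
from htpaint.core import CameraModel, LocalizationTable


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def filament_structure(camera):
    field_um = 48 * camera.pixel_size_nm / 1e3
    return sim.generate_structure("filaments", field_um,
                                  {"n_filaments": 6, "length_um": 5.0}, seed=3)


@pytest.fixture(scope="session")
def small_stack(filament_structure, camera):
    """Short low-density acquisition (48 px field, 300 frames)."""
    ev = sim.sample_binding_events(filament_structure, 0.109, 300,
                                   photon_rate=2000.0, seed=4)
    return sim.render_frames(ev, 1.2, camera, seed=5, bg_photons=10.0,
                             frame_shape=(48, 48))


def jittered_emitter_table(n_emitters=50, n_frames=150, jitter_px=0.1,
                           p_on=0.5, field_px=64, seed=0):
    """Fixed emitters re-localized with Gaussian jitter in random frames."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(4, field_px - 4, size=(n_emitters, 2))
    frames, xs, ys = [], [], []
    for f in range(n_frames):
        on = rng.random(n_emitters) < p_on
        pos = base[on] + rng.normal(0, jitter_px, size=(int(on.sum()), 2))
        frames.append(np.full(int(on.sum()), f))
        xs.append(pos[:, 0])
        ys.append(pos[:, 1])
    return LocalizationTable.from_arrays(
        frame=np.concatenate(frames), x=np.concatenate(xs), y=np.concatenate(ys),
        photons=1000.0, bg=10.0, sx=1.2, sy=1.2, lpx=jitter_px, lpy=jitter_px)
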