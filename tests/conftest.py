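import numpy as np
import pytest

from ctstrain.phantom import PhantomSpec, generate_phantom
from ctstrain.reslicing import LABEL_LA, LABEL_LV, LaxSlice


def smooth_spec(**kw):
    """Artifact-free phantom spec (no papillaries, texture or frame noise)."""
    base = dict(papillary_count=0, papillary_depth_mm=0.0,
                texture_amplitude_mm=0.0, frame_noise_mm=0.0)
    base.update(kw)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def smooth_phantom():
    """Uniform isotropic contraction to s(ES)=0.8, artifact-free."""
    return generate_phantom(smooth_spec(seed=1))


@pytest.fixture(scope="session")
def artifact_phantom():
    """Default conditions: papillaries, tissue texture, frame noise."""
    return generate_phantom(PhantomSpec(seed=3))


def disk_slice(radius_px: int, spacing: float = 1.0, size: int | None = None,
               la_cap_rows: int = 0) -> LaxSlice:
    """Digital disk LV slice; optionally the top ``la_cap_rows`` rows of
    the disk are relabelled LA (an atrium capping the ventricle)."""
    n = size or (2 * radius_px + 5)
    r, c = np.mgrid[:n, :n]
    cy = cx = n // 2
    mask = (r - cy) ** 2 + (c - cx) ** 2 <= radius_px**2
    labels = np.where(mask, LABEL_LV, 0).astype(np.uint8)
    if la_cap_rows:
        rows = np.nonzero(mask.any(axis=1))[0]
        cap = rows[:la_cap_rows]
        labels[cap] = np.where(mask[cap], LABEL_LA, 0)
    return LaxSlice(labels, spacing)


def ellipse_slice(a_mm: float, b_mm: float, spacing: float) -> LaxSlice:
    n = int(2 * max(a_mm, b_mm) / spacing) + 20
    r, c = np.mgrid[:n, :n]
    mask = (((c - n / 2) * spacing / a_mm) ** 2
            + ((r - n / 2) * spacing / b_mm) ** 2) <= 1
    return LaxSlice(mask.astype(np.uint8) * LABEL_LV, spacing)


def ramanujan_perimeter(a: float, b: float) -> float:
    h = (a - b) ** 2 / (a + b) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
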