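import numpy as np
import pytest

from sprintvision import RenderSpec, RunConfig, SprintProfile, render_cameras, simulate_profile


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_run():
    """A cheap two-camera, 20-m, constant 5 m/s rendered run with ground truth."""
    profile = SprintProfile.constant(5.0, track_length_m=20.0)
    spec = RenderSpec(
        marker_pixel_positions=((570.0, 70.0), (570.0, 70.0)),
        noise_sd=4.0,
        seed=11,
    )
    trajectory = simulate_profile(profile)
    return render_cameras(trajectory, spec, profile), profile


def brute_force_median(mask: np.ndarray, k: int) -> np.ndarray:
    """Naive sliding-window median with edge replication (test oracle)."""
    half = k // 2
    padded = np.pad(mask, half, mode="edge")
    out = np.zeros_like(mask)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            out[r, c] = np.median(padded[r : r + k, c : c + k])
    return out


def flood_fill_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components by explicit flood fill (test oracle)."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps
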