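"""Shared fixtures and independent oracles.

``brute_force_ps`` is a deliberately naive per-plaquette winding-number
computation (explicit Python loops, no convolution) used as the
independent oracle for the production detectors.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibrenew import synthetic_data as sd
from fibrenew.types import MMInfParams, SpiralDefect, SpiralScript


def _wrap(d: float) -> float:
    while d >= np.pi:
        d -= 2 * np.pi
    while d < -np.pi:
        d += 2 * np.pi
    return d


def brute_force_ps(frame: np.ndarray) -> list[tuple[float, float, int]]:
    """Per-plaquette winding oracle: loop over every 2x2 plaquette and
    sum wrapped phase differences around it with scalar arithmetic."""
    H, W = frame.shape
    found = []
    for i in range(H - 1):
        for j in range(W - 1):
            corners = [frame[i, j], frame[i, j + 1], frame[i + 1, j + 1],
                       frame[i + 1, j], frame[i, j]]
            total = 0.0
            for a, b in zip(corners[:-1], corners[1:]):
                total += _wrap(b - a)
            winding = int(round(total / (2 * np.pi)))
            if winding != 0:
                found.append((j + 0.5, i + 0.5, int(np.sign(winding))))
    return found


def loop_charge(frame: np.ndarray, margin: int = 1) -> int:
    """Total topological charge inside a rectangular loop ``margin``
    pixels in from the boundary, by direct line integration."""
    H, W = frame.shape
    path = []
    r0, r1, c0, c1 = margin, H - 1 - margin, margin, W - 1 - margin
    path += [(r0, c) for c in range(c0, c1 + 1)]
    path += [(r, c1) for r in range(r0 + 1, r1 + 1)]
    path += [(r1, c) for c in range(c1 - 1, c0 - 1, -1)]
    path += [(r, c0) for r in range(r1 - 1, r0 - 1, -1)]
    total = 0.0
    for (ra, ca), (rb, cb) in zip(path, path[1:] + path[:1]):
        total += _wrap(frame[rb, cb] - frame[ra, ca])
    return int(round(total / (2 * np.pi)))


def random_defect_frame(rng: np.random.Generator, shape=(24, 24), max_defects=3,
                        margin=4.0, min_sep=6.0):
    """A single frame with 1..max_defects well-separated planted defects;
    returns (frame, truth list of (x, y, chirality))."""
    H, W = shape
    n = int(rng.integers(1, max_defects + 1))
    truth = []
    for _ in range(n):
        for _try in range(200):
            x = rng.uniform(margin, W - 1 - margin)
            y = rng.uniform(margin, H - 1 - margin)
            if all(np.hypot(x - tx, y - ty) >= min_sep for tx, ty, _ in truth):
                q = int(rng.choice([-1, 1]))
                truth.append((x, y, q))
                break
    script = SpiralScript(
        [SpiralDefect(0, 1, np.array([tx, ty]), q) for tx, ty, q in truth],
        n_frames=1, omega=rng.uniform(0, 0.2))
    movie, _ = sd.make_spiral_phase_movie(script, shape)
    return movie.values[0], truth


@pytest.fixture(scope="session")
def coupled_fixture():
    """M/M/inf event stream rendered into a phase movie: the planted
    renewal process with known (lambda_f, lambda_d) plus its exact
    frame-quantized truth table."""
    params = MMInfParams(0.03, 0.01, 4000.0, seed=3)
    events = sd.simulate_mminf_events(params)
    script = sd.script_from_events(events, (32, 32), dt_ms=2.0, seed=7)
    movie, truth = sd.make_spiral_phase_movie(script, (32, 32), dt_ms=2.0)
    return params, movie, truth
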