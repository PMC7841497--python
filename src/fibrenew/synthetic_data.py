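"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here:

* M/M/inf event streams — homogeneous Poisson formations at rate
  ``lambda_f`` with independent exponential lifetimes at rate
  ``lambda_d`` (:func:`simulate_mminf_events`);
* phase movies with planted spiral-wave defects whose birth/death times,
  positions and chirality are known exactly
  (:func:`make_spiral_phase_movie`);
* a two-variable excitable medium (Aliev–Panfilov class) producing
  planar waves under an S1 stimulus and spiral re-entry under an S1–S2
  cross-shock (:func:`simulate_excitable_tissue`);
* unipolar electrograms contaminated by a ventricular far-field
  (QRS-like) artifact at known instants (:func:`make_synthetic_egm`);
* heterogeneous epoch cohorts for the sustained-vs-terminating
  contrast (:func:`simulate_cohort`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    EVENT_COLUMNS,
    EgmSet,
    EventTable,
    MMInfParams,
    ParameterError,
    PhaseMovie,
    SpiralDefect,
    SpiralScript,
    wrap_phase,
)

__all__ = [
    "simulate_mminf_events",
    "make_spiral_phase_movie",
    "script_from_events",
    "make_pair_script",
    "TissueParams",
    "simulate_excitable_tissue",
    "make_synthetic_egm",
    "default_qrs_template",
    "simulate_cohort",
]


def simulate_mminf_events(params: MMInfParams, kind: str = "PS") -> EventTable:
    """Simulate an M/M/inf birth-death event stream.

    Formations are a homogeneous Poisson process of rate
    ``params.lambda_f`` on ``[0, duration_ms)``; each entity draws an
    independent exponential lifetime with rate ``params.lambda_d``.
    Entities still alive at the epoch end are truncated there and
    flagged ``censored_right``.

    Locations are uniform on the unit square (declared in metadata);
    chirality is a fair ±1 coin for PS and 0 ("none") for wavelets.
    """
    if kind not in ("PS", "wavelet"):
        raise ParameterError(f"kind must be 'PS' or 'wavelet', got {kind!r}")
    rng = np.random.default_rng(params.seed)
    T = params.duration_ms
    n = rng.poisson(params.lambda_f * T)
    onsets = np.sort(rng.uniform(0.0, T, size=n))
    lifetimes = rng.exponential(1.0 / params.lambda_d, size=n)
    offsets = onsets + lifetimes
    censored_right = offsets > T
    offsets = np.minimum(offsets, T)
    if kind == "PS":
        chirality = rng.choice([-1, 1], size=n)
    else:
        chirality = np.zeros(n, dtype=int)
    xy = rng.uniform(0.0, 1.0, size=(n, 2))
    records = pd.DataFrame(
        {
            "id": np.arange(n),
            "kind": kind,
            "onset_ms": onsets,
            "offset_ms": offsets,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "chirality": chirality,
            "censored_left": np.zeros(n, dtype=bool),
            "censored_right": censored_right,
        },
        columns=EVENT_COLUMNS,
    )
    meta = {
        "generator": "simulate_mminf_events",
        "lambda_f": params.lambda_f,
        "lambda_d": params.lambda_d,
        "duration_ms": T,
        "seed": params.seed,
        "location_unit": "unit-square",
    }
    return EventTable(records, epoch_ms=T, metadata=meta)


def _script_truth_table(script: SpiralScript, dt_ms: float) -> EventTable:
    rows = []
    for i, d in enumerate(script.defects):
        x, y = d.path[0]
        rows.append(
            {
                "id": i,
                "kind": "PS",
                "onset_ms": d.birth_frame * dt_ms,
                "offset_ms": d.death_frame * dt_ms,
                "x": x,
                "y": y,
                "chirality": d.chirality,
                "censored_left": d.birth_frame == 0,
                "censored_right": d.death_frame >= script.n_frames,
            }
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EventTable(df, epoch_ms=script.n_frames * dt_ms,
                      metadata={"generator": "make_spiral_phase_movie"})


def make_spiral_phase_movie(
    script: SpiralScript,
    shape: tuple[int, int],
    dt_ms: float = 1.0,
    pixel_mm: float = 1.0,
) -> tuple[PhaseMovie, EventTable]:
    """Render a phase movie from a defect script, with exact truth.

    The frame-``t`` phase field is the wrapped angle of
    ``prod_i (z - z_i(t))**q_i * exp(-i omega t)`` with ``z`` the complex
    pixel coordinate ``x + i y`` — each live defect contributes a unit
    topological charge of sign ``q_i`` at its position, on top of a
    spatially uniform rotation.
    """
    H, W = shape
    if H < 8 or W < 8:
        raise ParameterError("shape must be at least 8 x 8")
    for d in script.defects:
        if (
            d.path[:, 0].min() < 1
            or d.path[:, 0].max() > W - 2
            or d.path[:, 1].min() < 1
            or d.path[:, 1].max() > H - 2
        ):
            raise ParameterError("defect path leaves the grid interior")
    yy, xx = np.mgrid[0:H, 0:W]
    values = np.empty((script.n_frames, H, W))
    for t in range(script.n_frames):
        ph = np.full((H, W), -script.omega * t * dt_ms)
        for d in script.defects:
            if d.alive(t):
                x0, y0 = d.position(t)
                ph = ph + d.chirality * np.arctan2(yy - y0, xx - x0)
        values[t] = wrap_phase(ph)
    movie = PhaseMovie(
        values,
        dt_ms=dt_ms,
        pixel_mm=pixel_mm,
        metadata={"generator": "make_spiral_phase_movie",
                  "omega": script.omega, "pair_mode": script.pair_mode},
    )
    return movie, _script_truth_table(script, dt_ms)


def script_from_events(
    events: EventTable,
    shape: tuple[int, int],
    dt_ms: float = 1.0,
    min_separation_px: float = 6.0,
    margin_px: float = 3.0,
    omega: float = 0.05,
    seed: int = 0,
) -> SpiralScript:
    """Plant one static defect per M/M/inf event, coupling the movie to
    the event stream's renewal statistics.

    Positions are drawn uniformly, rejecting draws closer than
    ``min_separation_px`` to any defect alive at an overlapping time so
    detections remain resolvable. Event times are quantized to frames
    (``birth = ceil(onset / dt)``, ``death = ceil(offset / dt)``).
    """
    H, W = shape
    rng = np.random.default_rng(seed)
    n_frames = int(np.ceil(events.epoch_ms / dt_ms))
    placed: list[tuple[int, int, np.ndarray]] = []  # (birth, death, xy)
    defects = []
    for rec in events.records.itertuples():
        birth = int(np.ceil(rec.onset_ms / dt_ms))
        death = int(np.ceil(rec.offset_ms / dt_ms))
        death = min(death, n_frames)
        if death <= birth:
            continue  # event too short to appear in any frame
        pos = None
        for _ in range(500):
            cand = np.array(
                [rng.uniform(margin_px, W - 1 - margin_px),
                 rng.uniform(margin_px, H - 1 - margin_px)])
            ok = all(
                not (birth < dth and b < death)
                or np.linalg.norm(cand - xy) >= min_separation_px
                for b, dth, xy in placed
            )
            if ok:
                pos = cand
                break
        if pos is None:
            continue  # medium saturated; drop the event (recorded below)
        placed.append((birth, death, pos))
        chir = int(rec.chirality) if rec.chirality in (-1, 1) else int(rng.choice([-1, 1]))
        defects.append(SpiralDefect(birth, death, pos, chir))
    return SpiralScript(defects, n_frames=n_frames, omega=omega, pair_mode=False)


def make_pair_script(
    n_pairs: int,
    n_frames: int,
    shape: tuple[int, int],
    separation_px: float = 5.0,
    margin_px: float = 4.0,
    omega: float = 0.05,
    seed: int = 0,
) -> SpiralScript:
    """Script whose defects are born and die as opposite-chirality
    pairs, so total planted charge is conserved at zero."""
    H, W = shape
    rng = np.random.default_rng(seed)
    defects = []
    for _ in range(n_pairs):
        birth = int(rng.integers(0, max(n_frames - 2, 1)))
        death = int(rng.integers(birth + 1, n_frames + 1))
        cx = rng.uniform(margin_px + separation_px, W - 1 - margin_px - separation_px)
        cy = rng.uniform(margin_px, H - 1 - margin_px)
        theta = rng.uniform(0, np.pi)
        dx = 0.5 * separation_px * np.cos(theta)
        dy = 0.5 * separation_px * np.sin(theta)
        defects.append(SpiralDefect(birth, death, np.array([cx - dx, cy - dy]), +1))
        defects.append(SpiralDefect(birth, death, np.array([cx + dx, cy + dy]), -1))
    return SpiralScript(defects, n_frames=n_frames, omega=omega, pair_mode=True)


# ---------------------------------------------------------------------------
# Two-variable excitable medium (Aliev–Panfilov class)
# ---------------------------------------------------------------------------


class TissueParams:
    """Aliev–Panfilov medium parameters.

    du/dt = k u (u - a)(1 - u) - u v + D lap(u)
    dv/dt = eps(u, v) * (-v - k u (u - a - 1)),  eps = eps0 + mu1 v / (u + mu2)

    ``time_scale_ms`` converts one dimensionless time unit into ms
    (12.9 ms is the conventional calibration of this model).
    """

    def __init__(
        self,
        shape: tuple[int, int] = (120, 120),
        a: float = 0.1,
        k: float = 8.0,
        eps0: float = 0.002,
        mu1: float = 0.2,
        mu2: float = 0.3,
        diffusion: float = 1.0,
        dx: float = 0.6,
        dt: float = 0.04,
        time_scale_ms: float = 12.9,
    ):
        self.shape = shape
        self.a, self.k = a, k
        self.eps0, self.mu1, self.mu2 = eps0, mu1, mu2
        self.diffusion, self.dx, self.dt = diffusion, dx, dt
        self.time_scale_ms = time_scale_ms
        if dt > dx * dx / (4.0 * diffusion):
            raise ParameterError(
                f"dt={dt} violates the diffusive stability bound "
                f"dx^2/(4D)={dx * dx / (4 * diffusion):.4f}")


def _laplacian(u: np.ndarray, dx: float) -> np.ndarray:
    # five-point stencil with no-flux (Neumann) boundaries
    up = np.empty_like(u)
    up[1:-1, 1:-1] = (
        u[:-2, 1:-1] + u[2:, 1:-1] + u[1:-1, :-2] + u[1:-1, 2:] - 4 * u[1:-1, 1:-1]
    )
    up[0, :] = up[1, :]
    up[-1, :] = up[-2, :]
    up[:, 0] = up[:, 1]
    up[:, -1] = up[:, -2]
    return up / (dx * dx)


def simulate_excitable_tissue(
    params: TissueParams | None = None,
    protocol: str = "S1S2",
    duration_units: float = 120.0,
    s2_time_units: float = 45.0,
    record_every: int = 25,
) -> tuple[np.ndarray, float]:
    """Integrate the two-variable medium under a pacing protocol.

    ``protocol`` is ``"S1"`` (planar wave from the left edge), ``"S1S2"``
    (cross-shock: a second stimulus over an interior patch in the wake
    of the S1 wave; delivered in the vulnerable window it breaks at both
    patch edges into a figure-of-eight pair of counter-rotating
    spirals), or ``"none"`` (resting medium). The default
    ``s2_time_units`` was tuned empirically to sit inside the vulnerable
    window of the default medium. Returns ``(voltage_movie, dt_ms)``
    with the movie sampled every ``record_every`` integration steps.
    """
    if params is None:
        params = TissueParams()
    if protocol not in ("S1", "S1S2", "none"):
        raise ParameterError(f"unknown protocol {protocol!r}")
    H, W = params.shape
    u = np.zeros((H, W))
    v = np.zeros((H, W))
    n_steps = int(round(duration_units / params.dt))
    s2_step = int(round(s2_time_units / params.dt))
    if protocol in ("S1", "S1S2"):
        u[:, :4] = 1.0  # S1: excite the left edge -> rightward planar wave
    frames = []
    for step in range(n_steps):
        if protocol == "S1S2" and step == s2_step:
            # S2 cross-shock: interior patch in the S1 wake
            u[H // 4: 3 * H // 4, W // 12: W // 2] = 1.0
        eps = params.eps0 + params.mu1 * v / (u + params.mu2)
        du = (
            params.k * u * (u - params.a) * (1.0 - u)
            - u * v
            + params.diffusion * _laplacian(u, params.dx)
        )
        dv = eps * (-v - params.k * u * (u - params.a - 1.0))
        u = u + params.dt * du
        v = v + params.dt * dv
        if step % record_every == 0:
            frames.append(u.copy())
    dt_ms = record_every * params.dt * params.time_scale_ms
    return np.array(frames), dt_ms


# ---------------------------------------------------------------------------
# Synthetic electrograms with a QRS-like far-field artifact
# ---------------------------------------------------------------------------


def default_qrs_template(fs_hz: float, width_ms: float = 80.0, amplitude: float = 3.0) -> np.ndarray:
    """Biphasic far-field deflection: derivative-of-Gaussian, ``width_ms`` long."""
    n = int(round(width_ms * fs_hz / 1000.0))
    t = np.linspace(-3.0, 3.0, n)
    tpl = -t * np.exp(-0.5 * t * t)
    return amplitude * tpl / np.abs(tpl).max()


def make_synthetic_egm(
    n_channels: int = 64,
    duration_ms: float = 4000.0,
    fs_hz: float = 2000.0,
    atrial_hz: float = 6.0,
    atrial_amplitude: float = 1.0,
    channel_phases: np.ndarray | None = None,
    r_times_ms: np.ndarray | None = None,
    qrs_template: np.ndarray | None = None,
    coords_mm: np.ndarray | None = None,
    seed: int = 0,
) -> EgmSet:
    """Atrial sinusoids plus a QRS-like template inserted at ``r_times_ms``.

    The clean atrial component is retained in metadata as ground truth
    for QRS-subtraction tests. Channel phase offsets default to a plane
    wave across an (approximately square) electrode grid.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_ms * fs_hz / 1000.0))
    t_ms = np.arange(n_samples) * 1000.0 / fs_hz
    side = int(np.ceil(np.sqrt(n_channels)))
    if coords_mm is None:
        gy, gx = np.divmod(np.arange(n_channels), side)
        coords_mm = np.column_stack([gx, gy]).astype(float) * 4.0
    if channel_phases is None:
        channel_phases = 2.0 * np.pi * coords_mm[:, 0] / (4.0 * side)
    atrial = atrial_amplitude * np.sin(
        2.0 * np.pi * atrial_hz * t_ms[None, :] / 1000.0 + channel_phases[:, None]
    )
    signals = atrial.copy()
    r_times = np.asarray(r_times_ms, dtype=float) if r_times_ms is not None else np.array([])
    if r_times.size:
        if qrs_template is None:
            qrs_template = default_qrs_template(fs_hz)
        half = len(qrs_template) // 2
        if r_times.size > 1:
            min_rr_samples = np.diff(np.sort(r_times)).min() * fs_hz / 1000.0
            if len(qrs_template) > min_rr_samples:
                raise ParameterError(
                    "QRS template longer than the minimum R-R interval "
                    "(overlapping insertions)")
        # far-field: common artifact with mild per-channel gain spread
        gains = 1.0 + 0.1 * rng.standard_normal(n_channels)
        for r in r_times:
            c = int(round(r * fs_hz / 1000.0))
            lo, hi = c - half, c - half + len(qrs_template)
            if lo < 0 or hi > n_samples:
                raise ParameterError(f"R-time {r} ms places template outside the record")
            signals[:, lo:hi] += gains[:, None] * qrs_template[None, :]
    return EgmSet(
        signals,
        fs_hz=fs_hz,
        coords_mm=coords_mm,
        r_times_ms=r_times if r_times.size else None,
        metadata={
            "generator": "make_synthetic_egm",
            "atrial_truth": atrial,
            "atrial_hz": atrial_hz,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Epoch cohorts for the sustained-vs-terminating contrast
# ---------------------------------------------------------------------------


def simulate_cohort(
    lambda_f: float,
    lambda_d: float,
    n_epochs: int,
    epoch_ms: float = 90_000.0,
    rate_cv: float = 0.35,
    rho_cv: float = 0.15,
    kind: str = "PS",
    seed: int = 0,
) -> list[EventTable]:
    """Generate a cohort of epochs with between-epoch rate heterogeneity.

    Each epoch draws its own (lambda_f, lambda_d): a lognormal
    multiplier with coefficient of variation ``rate_cv`` scales both
    rates together (patients differ mostly in overall tempo), and an
    independent lognormal multiplier with CV ``rho_cv`` perturbs the
    offered load lambda_f/lambda_d. Group-level means stay at the
    requested rates. Clinical basket-mapped cohorts show between-epoch
    spreads of roughly this size relative to their group means.
    """
    rng = np.random.default_rng(seed)
    sig_r = np.sqrt(np.log(1.0 + rate_cv**2))
    sig_rho = np.sqrt(np.log(1.0 + rho_cv**2))
    tables = []
    for i in range(n_epochs):
        tempo = rng.lognormal(-0.5 * sig_r**2, sig_r)
        load = rng.lognormal(-0.5 * sig_rho**2, sig_rho)
        ld_i = lambda_d * tempo
        lf_i = lambda_f * tempo * load
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = MMInfParams(lf_i, ld_i, epoch_ms, seed=sub_seed)
        tab = simulate_mminf_events(params, kind=kind)
        tab.metadata.update({"epoch_index": i, "cohort_seed": seed})
        tables.append(tab)
    return tables
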