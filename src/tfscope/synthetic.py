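"""Simulators with known ground truth for all three imaging analyses.

Each generator emulates the statistical structure one analysis assumes:

* fluctuation image stacks — Poisson focal-volume occupancy of species with
  brightness s*eps (compound Poisson counts, so var/mean = 1 + s*eps
  exactly), with optional photobleaching drift;
* single-molecule trajectories — a mixture of Brownian populations with
  localization error and 1-frame blinking;
* chromatin-binding dwell times — a two-exponential mixture with
  right-censoring and frame discretization;
* per-cell feature tables and textured nucleus crops with a controllable
  effect size between conditions.

All generators take an explicit integer seed; there is no global random
state, and identical seeds reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .nandb import ImageStack

__all__ = [
    "FfsSimParams",
    "TrackSimParams",
    "DwellSimParams",
    "FeatureSimParams",
    "simulate_ffs_stack",
    "simulate_tracks",
    "simulate_dwells",
    "simulate_feature_table",
    "simulate_nuclei_images",
]

# acquisition geometry used when none is specified: 41 nm pixels, 12.5 us dwell
DEFAULT_PIXEL_SIZE_UM = 0.041
DEFAULT_DWELL_TIME_US = 12.5


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass
class FfsSimParams:
    """Fluctuation-stack simulation parameters.

    ``species_mix`` lists ``(stoichiometry s, mean occupancy N_s)`` pairs:
    each species contributes molecules of brightness ``s * epsilon_monomer``
    counts per molecule per dwell, with Poisson occupancy of mean ``N_s``
    per focal volume (pixel).  ``bleach_fraction`` is the fractional
    intensity decay over the acquisition (linear ramp by default).
    """

    epsilon_monomer: float
    species_mix: list[tuple[int, float]]
    n_frames: int = 100
    shape: tuple[int, int] = (128, 128)
    bleach_fraction: float = 0.0
    bleach_mode: str = "linear"  # or "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon_monomer <= 0:
            raise ValueError("epsilon_monomer must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.bleach_fraction < 1:
            raise ValueError("bleach_fraction must lie in [0, 1)")
        if self.bleach_mode not in ("linear", "exponential"):
            raise ValueError("bleach_mode must be 'linear' or 'exponential'")
        for s, n_s in self.species_mix:
            if int(s) != s or s < 1:
                raise ValueError("stoichiometry must be an integer >= 1")
            if n_s < 0:
                raise ValueError("mean occupancy must be >= 0")
            if n_s * s * self.epsilon_monomer > 1e6:
                raise ValueError("overflow-scale parameters rejected")


@dataclass
class TrackSimParams:
    """Brownian-mixture trajectory simulation parameters.

    ``populations`` lists ``(D in um^2/s, weight)`` pairs; each track is
    assigned one population.  ``p_blink`` is the per-frame missed-detection
    probability (never two consecutive misses, matching a linking gap
    allowance of one frame).  ``n_frames`` spreads track start times over
    the movie; when None it is derived so that on average about five
    molecules are visible per frame.
    """

    populations: list[tuple[float, float]]
    sigma_loc: float = 0.03
    dt: float = 0.02
    n_tracks: int = 100
    mean_track_len: float = 20.0
    p_blink: float = 0.0
    fov: tuple[float, float] = (20.0, 20.0)
    n_frames: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        weights = [w for _, w in self.populations]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("population weights must sum to 1")
        if any(d < 0 for d, _ in self.populations):
            raise ValueError("diffusion coefficients must be >= 0")
        if not 0 <= self.p_blink < 1:
            raise ValueError("p_blink must lie in [0, 1)")
        if self.mean_track_len < 2:
            raise ValueError("mean_track_len must be >= 2")


@dataclass
class DwellSimParams:
    """Two-exponential dwell-time mixture with right-censoring.

    Durations are f*Exp(tau_long) + (1-f)*Exp(tau_short), discretized to
    multiples of the frame time dt (residence times are observed as frame
    counts), and right-censored at the observation limit t_max.
    """

    tau_short: float = 1.0
    tau_long: float = 12.0
    frac_long: float = 0.3
    n_dwells: int = 2000
    t_max: float = 250.0
    dt: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau_long > self.tau_short > 0:
            raise ValueError("require tau_long > tau_short > 0")
        if not 0 <= self.frac_long <= 1:
            raise ValueError("frac_long must lie in [0, 1]")
        if self.t_max < self.dt:
            raise ValueError("t_max must be at least the frame time dt")


@dataclass
class FeatureSimParams:
    """Gaussian per-cell feature tables with a controllable effect size.

    Each condition's mean is shifted by ``effect_size`` (in SD units) along
    a fixed random unit direction; cells are drawn from a multivariate
    Gaussian with that mean.  ``within_cov`` is either None (identity), a
    correlation level rho in (-1, 1) (equicorrelated unit variances), or a
    vector of per-feature variances.
    """

    conditions: list[str] = field(default_factory=lambda: ["ctrl", "treated"])
    n_cells_per_condition: int = 200
    n_features: int = 30
    effect_size: float = 1.0
    within_cov: float | list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_condition < 2:
            raise ValueError("n_cells_per_condition must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.effect_size > 0 and len(self.conditions) < 2:
            raise ValueError("separability requires at least 2 conditions")


# ---------------------------------------------------------------------------
# FFS stacks
# ---------------------------------------------------------------------------

def _bleach_ramp(params: FfsSimParams) -> np.ndarray:
    t = np.arange(params.n_frames) / max(params.n_frames - 1, 1)
    if params.bleach_fraction == 0:
        return np.ones(params.n_frames)
    if params.bleach_mode == "linear":
        return 1.0 - params.bleach_fraction * t
    k = -np.log(1.0 - params.bleach_fraction)
    return np.exp(-k * t)


def simulate_ffs_stack(params: FfsSimParams) -> tuple[ImageStack, dict]:
    """Simulate a photon-count fluctuation stack with known brightness.

    Per pixel and frame, each species' occupancy is Poisson with mean
    ``N_s * a(t)`` (the bleach ramp a(t) models fluorophores going dark)
    and detected counts are Poisson with mean ``occupancy * s * eps``.
    The compound is super-Poissonian with var/mean = 1 + s*eps exactly for
    a pure, bleach-free species.  Returns the stack plus a ground-truth
    record (eps, mix, bleach, ramp).
    """
    rng = np.random.default_rng(params.seed)
    ramp = _bleach_ramp(params)
    shape = (params.n_frames, *params.shape)
    data = np.zeros(shape, dtype=np.int64)
    for s, n_s in params.species_mix:
        if n_s == 0:
            continue
        occ = rng.poisson(n_s * ramp[:, None, None], size=shape)
        data += rng.poisson(occ * (s * params.epsilon_monomer))
    stack = ImageStack(
        data.astype(np.uint16) if data.max() < 2**16 else data,
        pixel_size=DEFAULT_PIXEL_SIZE_UM,
        dwell_time=DEFAULT_DWELL_TIME_US,
    )
    truth = {
        "epsilon_monomer": params.epsilon_monomer,
        "species_mix": list(params.species_mix),
        "bleach_fraction": params.bleach_fraction,
        "bleach_mode": params.bleach_mode,
        "expected_B": {
            int(s): 1.0 + s * params.epsilon_monomer for s, _ in params.species_mix
        },
        "ramp": ramp,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def simulate_tracks(
    params: TrackSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate 2-D Brownian trajectories from a population mixture.

    Returns ``(localizations, truth_tracks, truth)``: the localization
    table (frame, x_um, y_um, intensity — identities stripped) and the
    ground-truth linked table (track_id, frame, x_um, y_um) share row
    order, so row i of one corresponds to row i of the other.  Positions
    include localization noise; frames are dropped by blinking (at most
    one consecutive miss).
    """
    rng = np.random.default_rng(params.seed)
    n_pop = len(params.populations)
    weights = np.array([w for _, w in params.populations])
    d_values = np.array([d for d, _ in params.populations])
    pop = rng.choice(n_pop, size=params.n_tracks, p=weights)
    # min length 2; geometric tail gives mean mean_track_len
    p_geo = 1.0 / max(params.mean_track_len - 1.0, 1.0)
    lengths = 1 + rng.geometric(p_geo, size=params.n_tracks)
    n_frames = params.n_frames
    if n_frames is None:
        n_frames = max(int(np.ceil(params.n_tracks * lengths.mean() / 5.0)), int(lengths.max()))
    rows = []
    for tid in range(params.n_tracks):
        length = int(lengths[tid])
        d = d_values[pop[tid]]
        start_frame = int(rng.integers(0, max(n_frames - length, 0) + 1))
        x0 = rng.uniform(0, params.fov[0])
        y0 = rng.uniform(0, params.fov[1])
        steps = rng.normal(0.0, np.sqrt(2.0 * d * params.dt), size=(length - 1, 2))
        xy = np.vstack([[x0, y0], steps]).cumsum(axis=0)
        noisy = xy + rng.normal(0.0, params.sigma_loc, size=xy.shape)
        visible = np.ones(length, dtype=bool)
        if params.p_blink > 0:
            draws = rng.random(length)
            for i in range(length):
                if draws[i] < params.p_blink and (i == 0 or visible[i - 1]):
                    visible[i] = False
        for i in np.nonzero(visible)[0]:
            rows.append(
                (tid, start_frame + i, noisy[i, 0], noisy[i, 1])
            )
    truth_tracks = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    truth_tracks = truth_tracks.sort_values(
        ["frame", "x_um", "y_um"], kind="mergesort"
    ).reset_index(drop=True)
    locs = truth_tracks[["frame", "x_um", "y_um"]].copy()
    locs["intensity"] = 1.0
    truth = {
        "populations": list(params.populations),
        "population_of_track": pop,
        "D_of_track": d_values[pop],
        "track_length": lengths,
        "n_frames": n_frames,
        "sigma_loc": params.sigma_loc,
        "dt": params.dt,
    }
    return locs, truth_tracks, truth


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def simulate_dwells(params: DwellSimParams) -> pd.DataFrame:
    """Draw right-censored, frame-discretized two-exponential dwell times.

    Returns a table with columns ``duration_s`` (multiples of dt, capped at
    t_max) and ``censored`` (True where the underlying duration reached
    t_max before ending).
    """
    rng = np.random.default_rng(params.seed)
    is_long = rng.random(params.n_dwells) < params.frac_long
    tau = np.where(is_long, params.tau_long, params.tau_short)
    raw = rng.exponential(tau)
    # a binding event spanning k frames is observed as k * dt, at least 1 frame
    frames = np.maximum(np.ceil(raw / params.dt), 1.0)
    duration = frames * params.dt
    censored = duration >= params.t_max
    duration = np.minimum(duration, params.t_max)
    return pd.DataFrame({"duration_s": duration, "censored": censored})


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def _within_cholesky(params: FeatureSimParams) -> np.ndarray:
    p = params.n_features
    if params.within_cov is None:
        return np.eye(p)
    if np.isscalar(params.within_cov):
        rho = float(params.within_cov)
        cov = np.full((p, p), rho) + (1.0 - rho) * np.eye(p)
    else:
        cov = np.diag(np.asarray(params.within_cov, dtype=float))
    return np.linalg.cholesky(cov)


def simulate_feature_table(
    params: FeatureSimParams,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell Gaussian feature table with condition labels.

    Each condition's mean sits at ``effect_size`` SD along its own fixed
    random unit direction (condition 0 stays at the origin), so conditions
    are separable to a degree controlled by effect_size.
    """
    rng = np.random.default_rng(params.seed)
    p = params.n_features
    chol = _within_cholesky(params)
    directions = {}
    blocks = []
    for cond in params.conditions:
        u = rng.normal(size=p)
        u /= np.linalg.norm(u)
        directions[cond] = u
        z = rng.normal(size=(params.n_cells_per_condition, p))
        cells = z @ chol.T + params.effect_size * u
        df = pd.DataFrame(cells, columns=[f"f_{j:03d}" for j in range(p)])
        df.insert(0, "condition", cond)
        blocks.append(df)
    table = pd.concat(blocks, ignore_index=True)
    table.insert(0, "cell_id", [f"cell_{i:05d}" for i in range(len(table))])
    truth = {"directions": directions, "effect_size": params.effect_size}
    return table, truth


# ---------------------------------------------------------------------------
# textured nuclei
# ---------------------------------------------------------------------------

def simulate_nuclei_images(
    conditions: list[str],
    texture_scale: dict[str, float] | list[float],
    n: int = 60,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    ellipse_axes: tuple[float, float] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], list[str]]:
    """Generate labelled single-nucleus crops with condition-specific texture.

    Each crop is an elliptical nucleus mask filled with a Gaussian random
    field smoothed to the condition's correlation length (``texture_scale``
    in pixels) and rescaled to a fixed 0–255 intensity range.  Returns
    (crops, masks, labels), ``n`` of each per condition.
    """
    if isinstance(texture_scale, dict):
        scales = {c: texture_scale[c] for c in conditions}
    else:
        scales = dict(zip(conditions, texture_scale))
    for c, s in scales.items():
        if s <= 0:
            raise ValueError(f"texture_scale for {c!r} must be > 0")
    h, w = shape
    if ellipse_axes is None:
        ellipse_axes = (0.38 * h, 0.38 * w)
    if 2 * ellipse_axes[0] >= h or 2 * ellipse_axes[1] >= w:
        raise ValueError("crop shape is smaller than the nucleus ellipse")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (
        ((yy - (h - 1) / 2.0) / ellipse_axes[0]) ** 2
        + ((xx - (w - 1) / 2.0) / ellipse_axes[1]) ** 2
    ) <= 1.0
    rng = np.random.default_rng(seed)
    crops: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    labels: list[str] = []
    for cond in conditions:
        sigma = scales[cond]
        for _ in range(n):
            field_ = gaussian_filter(rng.normal(size=shape), sigma=sigma)
            inside = field_[mask]
            lo, hi = inside.min(), inside.max()
            span = hi - lo if hi > lo else 1.0
            img = np.zeros(shape)
            img[mask] = (field_[mask] - lo) / span * 255.0
            crops.append(img)
            masks.append(mask.copy())
            labels.append(cond)
    return crops, masks, labels
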