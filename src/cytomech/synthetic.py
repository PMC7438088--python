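"""Synthetic single-cell datasets with the statistical structure of the emulated treatment groups.

Every assay consumed by the analysis modules can be generated here with
known ground truth: per-group populations of hydraulic permeability,
osmotically active water fraction, radius and elastic modulus; volume
traces under the hyper/hypo-osmotic protocol with multiplicative radius
measurement noise; rendered image stacks of soft-edged disks; star-shaped
masks with controlled protrusions; Hertz force curves with contact offsets
and force noise; and correlated two-channel image pairs for colocalization
scoring.

Group presets hard-code only reported group statistics (means ± SD);
quantities with no reported numeric value are left ``None`` and must be
supplied by the user.  All generators are deterministic under
a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import draw

from .hertz import ForceCurve, hertz_force
from .osmotic import (
    CellParams,
    CellVolumeTrace,
    ModelConstants,
    OsmoticProtocol,
    simulate_volume_response,
)

__all__ = [
    "GroupPreset",
    "GROUP_PRESETS",
    "NoiseModel",
    "sample_population",
    "make_volume_traces",
    "render_frame_sequence",
    "make_shape_masks",
    "make_force_curves",
    "make_channel_pair",
    "PlacementError",
]

LP_UNIT = 1e-14  # presets quote L_p in units of 1e-14 m^3/(N s)


class PlacementError(ValueError):
    """Requested cells cannot be placed in the field without overlap."""


@dataclass(frozen=True)
class GroupPreset:
    """Reported population statistics for one treatment group.

    ``lp_*`` are (mean, SD) in 1e-14 m³/(N·s); ``radius`` in μm;
    ``modulus`` in kPa.  ``circularity_rel`` and ``pmlc_rel`` are
    means normalized to the untreated group.  ``None`` marks quantities
    with no reported numeric value.
    """

    name: str
    lp_hyper: tuple[float, float] | None
    lp_hypo: tuple[float, float] | None
    radius: tuple[float, float | None] | None
    modulus: tuple[float, float] | None
    circularity_rel: float | None
    pmlc_rel: float | None
    phi_ir: float = 0.6  # water fractions are reported only graphically

    def require(self, field_name: str) -> tuple:
        value = getattr(self, field_name)
        if value is None or (isinstance(value, tuple) and value[1] is None):
            raise ValueError(
                f"group '{self.name}' has no reported value for '{field_name}'"
            )
        return value


GROUP_PRESETS: dict[str, GroupPreset] = {
    "untreated": GroupPreset(
        "untreated",
        lp_hyper=(7.2, 1.4), lp_hypo=(8.8, 1.4),
        radius=(9.1, 1.3), modulus=(1.86, 0.91),
        circularity_rel=1.0, pmlc_rel=1.0,
    ),
    "TNFa": GroupPreset(
        "TNFa",
        lp_hyper=(10.5, 1.3), lp_hypo=(10.4, 1.3),
        radius=(9.9, 1.5), modulus=(1.04, 0.52),
        circularity_rel=0.746, pmlc_rel=0.804,
    ),
    "blebbistatin": GroupPreset(
        "blebbistatin",
        lp_hyper=(10.0, 2.1), lp_hypo=None,
        radius=(9.5, 1.4), modulus=(1.05, 0.51),
        circularity_rel=0.839, pmlc_rel=None,
    ),
    "Y27632": GroupPreset(
        "Y27632",
        lp_hyper=(8.3, 2.7), lp_hypo=None,
        radius=(9.5, 1.3), modulus=(1.09, 0.53),
        circularity_rel=0.836, pmlc_rel=None,
    ),
    "ML7": GroupPreset(
        "ML7",
        lp_hyper=(7.7, 2.9), lp_hypo=None,
        radius=(9.12, 1.3), modulus=(2.25, 1.72),
        circularity_rel=None, pmlc_rel=None,
    ),
    # no SD-scale spread is reported for this group's radius
    "CN03+TNFa": GroupPreset(
        "CN03+TNFa",
        lp_hyper=(4.4, 2.0), lp_hypo=(5.9, 2.9),
        radius=(9.5, None), modulus=(1.65, 0.88),
        circularity_rel=1.167, pmlc_rel=1.123,
    ),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings shared by the generators.

    ``radius_cv``: per-frame multiplicative radius noise (fraction).
    ``force_sd_frac``: additive force noise as a fraction of peak force.
    ``background_level``/``image_noise_sd``: rendered-frame background and
    additive Gaussian noise (grayscale units).
    """

    radius_cv: float = 0.05
    force_sd_frac: float = 0.05
    background_level: float = 100.0
    image_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if min(self.radius_cv, self.force_sd_frac, self.image_noise_sd) < 0:
            raise ValueError("noise magnitudes must be non-negative")


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    lower: float = 0.0,
    upper: float = np.inf,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_population(
    preset: GroupPreset,
    n: int,
    seed: int,
    c_ref: float = 333.0,
) -> pd.DataFrame:
    """Draw per-cell ground truths for one treatment group.

    Truncated-normal draws at the reported mean/SD (truncation at physical
    bounds: positive L_p, radius and modulus; φ_ir in [0, 1]).  Returns a
    table with columns cell_id, lp_hyper_m3Ns, lp_hypo_m3Ns, phi_ir,
    radius_um, modulus_kPa.  Raises if a required preset entry is null.
    """
    if n < 1:
        raise ValueError("population size must be at least 1")
    rng = np.random.default_rng(seed)
    lp_h_mean, lp_h_sd = preset.require("lp_hyper")
    rad_mean, rad_sd = preset.require("radius")
    mod_mean, mod_sd = preset.require("modulus")
    lp_hyper = _truncated_normal(rng, lp_h_mean, lp_h_sd, n) * LP_UNIT
    if preset.lp_hypo is not None:
        lp_o_mean, lp_o_sd = preset.lp_hypo
        lp_hypo = _truncated_normal(rng, lp_o_mean, lp_o_sd, n) * LP_UNIT
    else:
        lp_hypo = lp_hyper.copy()
    radius = _truncated_normal(rng, rad_mean, rad_sd, n, lower=1.0)
    modulus = _truncated_normal(rng, mod_mean, mod_sd, n, lower=0.05)
    phi_ir = np.full(n, preset.phi_ir)
    return pd.DataFrame(
        {
            "cell_id": [f"{preset.name}_{i:03d}" for i in range(n)],
            "group": preset.name,
            "lp_hyper_m3Ns": lp_hyper,
            "lp_hypo_m3Ns": lp_hypo,
            "phi_ir": phi_ir,
            "radius_um": radius,
            "modulus_kPa": modulus,
            "c_ir_mOsm": np.full(n, c_ref),
        }
    )


def params_from_row(row: pd.Series) -> CellParams:
    """Build osmotic-model parameters from one population-table row."""
    return CellParams(
        lp=(float(row.lp_hyper_m3Ns), float(row.lp_hypo_m3Ns)),
        phi_ir=float(row.phi_ir),
        radius_ref=float(row.radius_um) * 1e-6,
        c_ir=float(row.c_ir_mOsm),
    )


def make_volume_traces(
    population: pd.DataFrame,
    protocol: OsmoticProtocol,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    constants: ModelConstants = ModelConstants(),
    sampling_interval: float = 2.0,
) -> list[CellVolumeTrace]:
    """Forward-simulate noisy volume traces for a sampled population.

    Each cell is integrated with its per-step L_p truths; the measured
    radius gets i.i.d. multiplicative Gaussian noise per frame and the
    observed volume is its cube (volume is what the downstream fit sees).
    """
    rng = np.random.default_rng(seed)
    traces = []
    for _, row in population.iterrows():
        clean = simulate_volume_response(
            params_from_row(row),
            protocol,
            constants,
            sampling_interval=sampling_interval,
            cell_id=str(row.cell_id),
        )
        if noise.radius_cv > 0:
            radius = (clean.volume * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
            radius = radius * (1.0 + noise.radius_cv * rng.standard_normal(len(radius)))
            volume = 4.0 / 3.0 * math.pi * radius**3
        else:
            volume = clean.volume
        traces.append(
            CellVolumeTrace(
                cell_id=clean.cell_id,
                time=clean.time,
                volume=volume,
                step_index=clean.step_index,
                sampling_interval=sampling_interval,
            )
        )
    return traces


def _add_soft_disk(frame: np.ndarray, cy: float, cx: float, r_px: float,
                   edge_px: float, amplitude: float) -> None:
    """Add a disk with a sigmoidal edge crossing 50% at radius r_px."""
    shape = frame.shape
    y0, y1 = int(max(cy - r_px - 6 * edge_px, 0)), int(min(cy + r_px + 6 * edge_px + 1, shape[0]))
    x0, x1 = int(max(cx - r_px - 6 * edge_px, 0)), int(min(cx + r_px + 6 * edge_px + 1, shape[1]))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    frame[y0:y1, x0:x1] += amplitude / (1.0 + np.exp((d - r_px) / edge_px))


def render_frame_sequence(
    radii_um: np.ndarray,
    pixel_size: float = 0.2,
    field_shape: tuple[int, int] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    amplitude: float = 150.0,
    edge_px: float = 1.5,
    margin_px: int = 12,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render disks on a grid of non-overlapping positions.

    ``radii_um`` has shape (n_frames, n_cells) — each column is one cell
    through time (a single row renders a static field).  Cells keep their
    position across frames.  Returns a float stack (frames, H, W) and the
    ground-truth table (frame, cell, centroid, radius).  Raises
    :class:`PlacementError` when the requested cells do not fit.
    """
    radii_um = np.atleast_2d(np.asarray(radii_um, dtype=float))
    n_frames, n_cells = radii_um.shape
    rng = np.random.default_rng(seed)

    r_max_px = radii_um.max() / pixel_size if n_cells else 0.0
    pitch = int(math.ceil(2 * r_max_px + 2 * margin_px))
    if field_shape is None:
        side = int(math.ceil(math.sqrt(n_cells)))
        field_shape = (side * pitch + pitch, side * pitch + pitch)
    rows = max((field_shape[0] - pitch) // pitch, 0)
    cols = max((field_shape[1] - pitch) // pitch, 0)
    if rows * cols < n_cells:
        raise PlacementError(
            f"field {field_shape} fits {rows * cols} cells of radius "
            f"{r_max_px:.0f}px, {n_cells} requested"
        )
    jitter = rng.uniform(-margin_px / 2, margin_px / 2, size=(n_cells, 2))
    positions = []
    for i in range(n_cells):
        gy, gx = divmod(i, cols)
        positions.append(
            (
                pitch * (gy + 1) + jitter[i, 0],
                pitch * (gx + 1) + jitter[i, 1],
            )
        )

    stack = np.empty((n_frames,) + field_shape)
    truth_rows = []
    for fi in range(n_frames):
        frame = np.full(field_shape, noise.background_level)
        for ci in range(n_cells):
            cy, cx = positions[ci]
            r_px = radii_um[fi, ci] / pixel_size
            _add_soft_disk(frame, cy, cx, r_px, edge_px, amplitude)
            truth_rows.append(
                {
                    "frame": fi,
                    "cell": ci,
                    "centroid_y_px": cy,
                    "centroid_x_px": cx,
                    "radius_um": radii_um[fi, ci],
                }
            )
        if noise.image_noise_sd > 0:
            frame = frame + rng.normal(0.0, noise.image_noise_sd, field_shape)
        stack[fi] = frame
    return stack, pd.DataFrame(truth_rows)


def star_polygon(
    radius_px: float,
    amplitude: float,
    lobes: int,
    n_vertices: int = 720,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Polar star shape r(θ) = a·(1 + amplitude·cos(k θ)) as a polygon."""
    if amplitude >= 1.0 or amplitude < 0.0:
        raise ValueError("protrusion amplitude must lie in [0, 1)")
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = radius_px * (1.0 + amplitude * np.cos(lobes * theta))
    return np.stack(
        [center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)], axis=1
    )


def make_shape_masks(
    n: int,
    amplitude: float,
    lobes: int = 5,
    radius_px: tuple[float, float] = (40.0, 5.0),
    seed: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Rasterized star-shaped masks with analytic ground-truth circularity.

    Amplitude 0 yields disks.  The truth table reports the continuous
    polygon's area, perimeter and isoperimetric quotient, so rasterization
    bias of downstream measurements can be quantified.
    """
    if n < 1:
        raise ValueError("need n >= 1 masks")
    rng = np.random.default_rng(seed)
    radii = _truncated_normal(rng, radius_px[0], radius_px[1], n, lower=5.0)
    masks, rows = [], []
    for i, a_px in enumerate(radii):
        r_out = a_px * (1.0 + amplitude)
        size = int(2 * r_out + 10)
        poly = star_polygon(a_px, amplitude, lobes, center=(size / 2, size / 2))
        mask = draw.polygon2mask((size, size), poly)
        # continuous-shape references
        closed = np.vstack([poly, poly[:1]])
        seg = np.diff(closed, axis=0)
        perim = float(np.sqrt((seg**2).sum(axis=1)).sum())
        area = 0.5 * abs(
            float(np.sum(poly[:, 0] * np.roll(poly[:, 1], -1) - poly[:, 1] * np.roll(poly[:, 0], -1)))
        )
        masks.append(mask)
        rows.append(
            {
                "mask": i,
                "radius_px": a_px,
                "amplitude": amplitude,
                "lobes": lobes,
                "true_area_px2": area,
                "true_perimeter_px": perim,
                "true_circularity": 4.0 * math.pi * area / perim**2,
            }
        )
    return masks, pd.DataFrame(rows)


def make_force_curves(
    moduli_pa: np.ndarray,
    tip_radius: float = 3e-6,
    max_indentation: float = 1e-6,
    contact_offsets: np.ndarray | float = 1e-7,
    baseline: float = 0.0,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_points: int = 300,
    poisson_ratio: float = 0.5,
) -> list[ForceCurve]:
    """Hertz forward curves with a pre-contact baseline and additive noise.

    The z axis runs from 0 to ``contact offset + max indentation``; force
    is flat (baseline) before contact and Hertzian beyond it.  Noise SD is
    ``noise.force_sd_frac`` of each curve's peak force.
    """
    moduli_pa = np.atleast_1d(np.asarray(moduli_pa, dtype=float))
    if np.any(moduli_pa <= 0):
        raise ValueError("moduli must be positive")
    offsets = np.broadcast_to(
        np.asarray(contact_offsets, dtype=float), moduli_pa.shape
    )
    rng = np.random.default_rng(seed)
    curves = []
    for i, (e_pa, z_c) in enumerate(zip(moduli_pa, offsets)):
        z = np.linspace(0.0, z_c + max_indentation, n_points)
        delta = np.clip(z - z_c, 0.0, None)
        f = baseline + hertz_force(e_pa, poisson_ratio, tip_radius, delta)
        if noise.force_sd_frac > 0:
            peak = np.abs(f).max()
            f = f + rng.normal(0.0, noise.force_sd_frac * peak, n_points)
        curves.append(ForceCurve(z, f, tip_radius, cell_id=f"cell_{i:03d}"))
    return curves


def make_channel_pair(
    rho: float,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    mean: float = 100.0,
    sd: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two image channels with target in-mask Pearson correlation ``rho``.

    Channels are correlated Gaussian fields shifted to a positive intensity
    range; the mask is a centered disk covering most of the frame.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(shape)
    z2 = rng.standard_normal(shape)
    a = mean + sd * z1
    b = mean + sd * (rho * z1 + math.sqrt(1.0 - rho**2) * z2)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.45 * min(shape)) ** 2
    return a, b, mask
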