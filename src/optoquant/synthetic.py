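"""Synthetic gastrula-stage embryo volumes with programmed ground truth.

The generator emulates the statistical structure the quantification
pipeline assumes: a hemispherical cap of cells (animal pole up) on a dark
background, spherical non-overlapping nuclei, mosaic reporter (GFP)
expression in smoothed clonal patches, and a phospho-effector channel
whose expected intensity follows

    effector = baseline + gain * activation * reporter_expectation

optionally restricted to nuclei (nuclear effectors such as pSmad2) and to
an illuminated ROI box.  Additive Gaussian noise is clipped to
``[0, saturation_value]``.  Every output is a pure function of the truth
parameters and the seed.

Full experimental datasets (kinetics time courses, irradiance ladders)
are generated by driving the per-volume activation level with a
three-parameter logistic response, alongside matched dark controls; a
lightweight data-level simulator (:func:`simulate_response_points`)
produces dark-subtracted response points directly for fitting studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ChannelVolume, SampleMeta, save_manifest, write_volume
from .response import logistic3

__all__ = [
    "EmbryoTruth",
    "ResponseTruth",
    "ExperimentDesign",
    "generate_volume",
    "generate_response_dataset",
    "write_response_dataset",
    "simulate_response_points",
    "KINETICS_TIME_POINTS_MIN",
    "IRRADIANCE_LADDER_W_M2",
]

#: Fixation time points (min) used in the kinetics experiments.
KINETICS_TIME_POINTS_MIN = (0.0, 2.0, 8.0, 15.0, 22.0, 30.0, 35.0, 50.0, 60.0, 70.0, 85.0)

#: Irradiance ladder (W/m²), roughly 3-fold steps.
IRRADIANCE_LADDER_W_M2 = (0.0, 0.02, 0.05, 0.15, 0.46, 1.39, 4.17, 12.50, 50.00)


@dataclass(frozen=True)
class EmbryoTruth:
    """Ground-truth parameters of one synthetic embryo volume.

    ``gfp_field`` may be a scalar (uniform expression inside the embryo),
    a full (z, y, x) array of expected reporter intensity, or ``None`` to
    generate mosaic clonal patches from the seed.
    """

    n_nuclei: int = 110
    nucleus_radius_um: float = 12.0
    embryo_radius_um: float = 220.0
    gfp_field: float | np.ndarray | None = None
    gfp_level: float = 3000.0
    mosaic_fraction: float = 0.6
    patch_scale_um: float = 60.0
    effector_gain: float = 2.0
    baseline_effector: float = 200.0
    noise_sd: float = 50.0
    saturation_value: float = 65535.0
    seed: int = 0
    shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size_um: tuple[float, float, float] = (9.0, 5.0, 5.0)
    dapi_level: float = 20000.0
    dapi_background: float = 1500.0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        for name in ("nucleus_radius_um", "embryo_radius_um", "patch_scale_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(v <= 0 for v in self.voxel_size_um) or any(s <= 0 for s in self.shape):
            raise ValueError("shape and voxel_size_um entries must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.saturation_value <= self.baseline_effector:
            raise ValueError("saturation_value must exceed baseline_effector")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ResponseTruth:
    """Programmed three-parameter logistic response in time or irradiance."""

    a_true: float
    b_true: float
    c_true: float
    axis: Literal["time", "irradiance"] = "time"
    direction: Literal["on", "off"] = "on"

    def __post_init__(self) -> None:
        if self.c_true < 0:
            raise ValueError("c_true must be >= 0")
        if self.direction == "on" and self.a_true <= 0:
            raise ValueError("direction='on' requires a_true > 0")
        if self.direction == "off" and self.a_true >= 0:
            raise ValueError("direction='off' requires a_true < 0")

    def activation(self, x: float) -> float:
        """Programmed activation fraction y(x) / c at sample point x."""
        if self.c_true == 0:
            return 0.0
        return float(logistic3(np.asarray(x, float), self.a_true, self.b_true, 1.0))


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design: axis points, replicate counts, dark-control matching."""

    sample_points: tuple[float, ...]
    n_bio_replicates: int = 3
    n_technical: int = 1
    dark_controls: bool = True

    def __post_init__(self) -> None:
        pts = tuple(float(p) for p in self.sample_points)
        if not pts:
            raise ValueError("sample_points must be non-empty")
        if any(p < 0 for p in pts):
            raise ValueError("sample_points must be non-negative")
        if any(b <= a for a, b in zip(pts, pts[1:])) and len(pts) > 1:
            if not all(b > a for a, b in zip(pts, pts[1:])):
                raise ValueError("sample_points must be strictly increasing")
        object.__setattr__(self, "sample_points", pts)
        if self.n_bio_replicates < 1 or self.n_technical < 1:
            raise ValueError("replicate counts must be >= 1")


def _embryo_geometry(truth: EmbryoTruth):
    """Embryo-interior mask (hemispherical cap, z=0 at top) and µm coords."""
    nz, ny, nx = truth.shape
    dz, dy, dx = truth.voxel_size_um
    z = np.arange(nz)[:, None, None] * dz
    y = (np.arange(ny)[None, :, None] - (ny - 1) / 2) * dy
    x = (np.arange(nx)[None, None, :] - (nx - 1) / 2) * dx
    r2 = z**2 + y**2 + x**2
    embryo = r2 <= truth.embryo_radius_um**2
    return embryo, (z, y, x)


def _place_nuclei(truth: EmbryoTruth, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping sphere centres (µm) inside the cap, rejection sampled."""
    R = truth.embryo_radius_um
    r = truth.nucleus_radius_um
    centers: list[np.ndarray] = []
    max_attempts = 400 * max(truth.n_nuclei, 1)
    attempts = 0
    zmax = min(R, truth.shape[0] * truth.voxel_size_um[0])
    while len(centers) < truth.n_nuclei and attempts < max_attempts:
        attempts += 1
        cand = np.array(
            [
                rng.uniform(r, zmax - r if zmax > 2 * r else zmax),
                rng.uniform(-R, R),
                rng.uniform(-R, R),
            ]
        )
        if cand @ cand > (R - r) ** 2:
            continue
        if centers and np.min(np.linalg.norm(np.array(centers) - cand, axis=1)) < 2 * r:
            continue
        centers.append(cand)
    return np.array(centers) if centers else np.empty((0, 3))


def _nucleus_mask(truth: EmbryoTruth, centers: np.ndarray) -> np.ndarray:
    nz, ny, nx = truth.shape
    dz, dy, dx = truth.voxel_size_um
    mask = np.zeros(truth.shape, dtype=bool)
    r = truth.nucleus_radius_um
    for cz, cy, cx in centers:
        # voxel-index bounding box of the sphere
        iz0 = max(int((cz - r) / dz), 0)
        iz1 = min(int((cz + r) / dz) + 2, nz)
        cy_i = cy / dy + (ny - 1) / 2
        cx_i = cx / dx + (nx - 1) / 2
        iy0 = max(int(cy_i - r / dy), 0)
        iy1 = min(int(cy_i + r / dy) + 2, ny)
        ix0 = max(int(cx_i - r / dx), 0)
        ix1 = min(int(cx_i + r / dx) + 2, nx)
        if iz1 <= iz0 or iy1 <= iy0 or ix1 <= ix0:
            continue  # nucleus outside the imaged grid
        zz = np.arange(iz0, iz1)[:, None, None] * dz - cz
        yy = (np.arange(iy0, iy1)[None, :, None] - (ny - 1) / 2) * dy - cy
        xx = (np.arange(ix0, ix1)[None, None, :] - (nx - 1) / 2) * dx - cx
        mask[iz0:iz1, iy0:iy1, ix0:ix1] |= zz**2 + yy**2 + xx**2 <= r**2
    return mask


def _reporter_field(
    truth: EmbryoTruth, embryo: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Expected reporter intensity per voxel (AU), zero outside the embryo."""
    if truth.gfp_field is not None:
        if np.isscalar(truth.gfp_field):
            return np.where(embryo, float(truth.gfp_field), 0.0)
        arr = np.asarray(truth.gfp_field, dtype=float)
        if arr.shape != truth.shape:
            raise ValueError("gfp_field array shape must match truth.shape")
        return np.where(embryo, arr, 0.0)
    # mosaic clonal patches: smoothed white noise thresholded at the
    # (1 - mosaic_fraction) quantile within the embryo
    noise = rng.standard_normal(truth.shape)
    sigma = tuple(truth.patch_scale_um / v for v in truth.voxel_size_um)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma)
    inside = smooth[embryo]
    if inside.size == 0 or truth.mosaic_fraction == 0:
        return np.zeros(truth.shape)
    if truth.mosaic_fraction >= 1.0:
        expressing = embryo
    else:
        cut = np.quantile(inside, 1.0 - truth.mosaic_fraction)
        expressing = embryo & (smooth > cut)
    # mild smooth intensity variation within expressing clones (0.6–1.4x)
    lo, hi = smooth.min(), smooth.max()
    rel = (smooth - lo) / (hi - lo) if hi > lo else np.full(truth.shape, 0.5)
    return np.where(expressing, truth.gfp_level * (0.6 + 0.8 * rel), 0.0)


def generate_volume(
    truth: EmbryoTruth,
    activation_level: float = 0.0,
    effector_localization: Literal["nuclear", "broad"] = "broad",
    roi: tuple[int, int, int, int, int, int] | None = None,
) -> tuple[ChannelVolume, dict[str, np.ndarray]]:
    """Render one three-channel volume (DAPI, GFP, EFFECTOR) plus truth masks.

    Returns the volume and a dict of ground-truth boolean masks:
    ``embryo`` (cap interior), ``nuclei``, and ``reporter``
    (reporter-positive voxels).
    """
    if not 0.0 <= activation_level <= 1.0:
        raise ValueError("activation_level must be in [0, 1]")
    if roi is not None:
        z0, z1, y0, y1, x0, x1 = roi
        nz, ny, nx = truth.shape
        if not (0 <= z0 < z1 <= nz and 0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise ValueError(f"roi {roi} outside volume bounds {truth.shape}")

    rng = np.random.default_rng(truth.seed)
    embryo, _ = _embryo_geometry(truth)
    centers = _place_nuclei(truth, rng)
    nuclei = _nucleus_mask(truth, centers) & embryo
    reporter = _reporter_field(truth, embryo, rng)

    dapi = np.where(embryo, truth.dapi_background, 0.0)
    dapi[nuclei] = truth.dapi_level

    effector = np.full(truth.shape, truth.baseline_effector, dtype=float)
    drive = truth.effector_gain * activation_level * reporter
    if effector_localization == "nuclear":
        drive = np.where(nuclei, drive, 0.0)
    elif effector_localization != "broad":
        raise ValueError("effector_localization must be 'nuclear' or 'broad'")
    if roi is not None:
        z0, z1, y0, y1, x0, x1 = roi
        box = np.zeros(truth.shape, dtype=bool)
        box[z0:z1, y0:y1, x0:x1] = True
        drive = np.where(box, drive, 0.0)
    effector = effector + drive

    channels = np.stack([dapi, reporter, effector])
    if truth.noise_sd > 0:
        channels = channels + rng.normal(0.0, truth.noise_sd, channels.shape)
    channels = np.clip(np.round(channels), 0, truth.saturation_value)

    volume = ChannelVolume(
        voxels=channels.astype(np.uint16),
        channel_names=("DAPI", "GFP", "EFFECTOR"),
        voxel_size_um=truth.voxel_size_um,
        bit_depth=16,
    )
    masks = {"embryo": embryo, "nuclei": nuclei, "reporter": reporter > 0}
    return volume, masks


def _child_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ResponseDataset:
    """In-memory synthetic experiment: samples plus the programmed truth."""

    samples: list[tuple[SampleMeta, ChannelVolume]]
    truth: ResponseTruth
    design: ExperimentDesign
    embryo: EmbryoTruth
    tool: str

    @property
    def metadata(self) -> list[SampleMeta]:
        return [m for m, _ in self.samples]

    def truth_manifest(self) -> dict:
        d = asdict(self.embryo)
        if isinstance(d.get("gfp_field"), np.ndarray):
            d["gfp_field"] = "<array>"
        return {
            "response": asdict(self.truth),
            "design": asdict(self.design),
            "embryo": d,
            "tool": self.tool,
        }


def generate_response_dataset(
    truth: ResponseTruth,
    design: ExperimentDesign,
    embryo: EmbryoTruth,
    tool: str = "FGF",
    effector_localization: Literal["nuclear", "broad"] = "broad",
    light_condition: str = "455nm",
) -> ResponseDataset:
    """Generate a full image dataset driven by the programmed response.

    For each sample point x the activation level is the logistic value
    y(x)/c; matched dark controls (activation 0) are produced per sample
    point and replicate when the design asks for them.
    """
    samples: list[tuple[SampleMeta, ChannelVolume]] = []
    conditions = [(light_condition, True)] + ([("dark", False)] if design.dark_controls else [])
    for ip, x in enumerate(design.sample_points):
        act = truth.activation(x)
        for rep in range(design.n_bio_replicates):
            for tech in range(design.n_technical):
                for cond, lit in conditions:
                    seed = _child_seed(embryo.seed, ip, rep, tech, int(lit))
                    etruth = replace(embryo, seed=seed)
                    vol, _ = generate_volume(
                        etruth,
                        activation_level=act if lit else 0.0,
                        effector_localization=effector_localization,
                    )
                    meta = SampleMeta(
                        sample_id=f"{tool}_{cond}_x{ip:02d}_r{rep}_t{tech}",
                        tool=tool,
                        condition=cond,
                        axis_value=x,
                        bio_replicate=f"R{rep + 1}",
                    )
                    samples.append((meta, vol))
    return ResponseDataset(samples=samples, truth=truth, design=design, embryo=embryo, tool=tool)


def write_response_dataset(dataset: ResponseDataset, outdir: str | Path) -> Path:
    """Write a dataset to disk: OME-TIFF per sample, manifest CSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas = []
    for meta, vol in dataset.samples:
        fname = f"{meta.sample_id}.ome.tif"
        write_volume(outdir / fname, vol)
        meta.path = fname
        metas.append(meta)
    save_manifest(outdir / "manifest.csv", metas)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset.truth_manifest(), fh, indent=2)
    return outdir


def simulate_response_points(
    truth: ResponseTruth,
    design: ExperimentDesign,
    noise_sd: float = 0.0,
    seed: int = 0,
    rep_effect_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate dark-subtracted normalized response points directly.

    Skips image rendering: each (sample point, biological replicate) mean
    is the logistic value plus additive Gaussian noise, optionally with a
    replicate-level random offset.  Returns a tidy frame with columns
    ``x``, ``y``, ``bio_replicate``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    rep_offsets = rng.normal(0.0, rep_effect_sd, design.n_bio_replicates)
    for rep in range(design.n_bio_replicates):
        for x in design.sample_points:
            y = truth.c_true * truth.activation(x) + rep_offsets[rep]
            y += rng.normal(0.0, noise_sd)
            rows.append({"x": x, "y": y, "bio_replicate": f"R{rep + 1}"})
    return pd.DataFrame(rows)
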