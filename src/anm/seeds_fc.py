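"""Coactivation seeds and participant-level seed-to-voxel Fisher z maps.

A study's *coactivation seed* is the union of fixed-radius spheres (6 mm by
default) centred on every peak the study reported, intersected with the
brain mask.  For each participant of the normative connectome and each
seed, the seed's mean time series is correlated with every in-mask voxel's
time series (Pearson r) and Fisher z-transformed (atanh), yielding one
participant-level connectivity map per (participant, study) pair.

Sphere membership is evaluated in world millimetres on voxel centers
(closed ball, <= radius), never in voxel units, so anisotropic grids are
handled correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volumes import (
    BrainMask,
    ScalarVolume,
    VolumeGrid,
    check_same_grid,
    volume_from_vector,
)

logger = logging.getLogger(__name__)

#: |r| is clipped to 1 - R_CLIP_EPS before atanh so z stays finite.
R_CLIP_EPS = 1e-7


class EmptySeedError(ValueError):
    """A coactivation seed has no in-mask voxels."""


@dataclass
class CoactivationSeed:
    """Union of per-focus spheres for one study, on the pipeline grid."""

    study_id: str
    group: str
    mask: ScalarVolume  # kind="binary"

    def __post_init__(self) -> None:
        if self.mask.kind != "binary":
            raise ValueError("seed mask must be a binary volume")
        if self.n_voxels < 1:
            raise EmptySeedError(f"study {self.study_id}: coactivation seed is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.data.sum())

    @property
    def grid(self) -> VolumeGrid:
        return self.mask.grid


@dataclass
class ParticipantTimeSeries:
    """One connectome participant's in-mask voxel time series.

    ``data`` is a T x V matrix: T timepoints by V in-mask voxels, with
    columns in the pipeline-wide voxel ordering (C-order flat indices of
    the brain mask).
    """

    participant_id: str
    grid: VolumeGrid
    mask: BrainMask
    data: np.ndarray

    def __post_init__(self) -> None:
        check_same_grid(self.grid, self.mask.grid, "participant time series and mask")
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("time-series data must be T x V")
        if data.shape[0] < 8:
            raise ValueError(f"participant {self.participant_id}: need >= 8 timepoints, got {data.shape[0]}")
        if data.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"participant {self.participant_id}: {data.shape[1]} voxel columns "
                f"but mask has {self.mask.n_voxels} voxels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError(f"participant {self.participant_id}: non-finite time-series values")
        self.data = data

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[0])


@dataclass
class FisherZMap:
    """Seed-to-voxel Fisher z connectivity of one participant for one study.

    Values are stored as an in-mask vector (pipeline voxel ordering);
    ``volume`` materialises the full 3D map with zeros outside the mask.
    """

    participant_id: str
    study_id: str
    mask: BrainMask
    values: np.ndarray
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.mask.n_voxels,):
            raise ValueError("values must be one per in-mask voxel")
        if not np.all(np.isfinite(values)):
            raise ValueError("Fisher z values must be finite")
        self.values = values

    @property
    def volume(self) -> ScalarVolume:
        return volume_from_vector(self.values, self.mask, kind="z")


def make_sphere(
    center,
    radius: float,
    grid: VolumeGrid,
    brain_mask: BrainMask | None = None,
) -> np.ndarray:
    """Binary volume of voxels whose centers lie within ``radius`` mm of ``center``.

    The center is a world-mm point and need not coincide with a voxel
    center.  Membership is a closed ball (distance <= radius) intersected
    with the brain mask when one is given.  Returns a boolean array of
    ``grid.shape``; an all-false result (sphere entirely off-mask or
    off-grid) is returned with a warning, for the caller to handle.
    """
    if radius <= 0:
        raise ValueError(f"sphere radius must be > 0, got {radius}")
    if brain_mask is not None:
        check_same_grid(grid, brain_mask.grid, "sphere grid and brain mask")
    center = np.asarray(center, dtype=float)

    # Bounding box in voxel space: corners of the world-space cube around the
    # center, mapped through the inverse affine (handles oblique affines).
    offs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    corners = grid.world_to_voxel(center + radius * offs)
    lo = np.maximum(np.floor(corners.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(corners.max(axis=0)).astype(int) + 2, np.asarray(grid.shape))

    out = np.zeros(grid.shape, dtype=bool)
    if np.any(lo >= hi):
        logger.warning("sphere at %s (r=%g mm) lies entirely outside the grid", center, radius)
        return out
    ii, jj, kk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    box = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid.voxel_to_world(box) - center, axis=1)
    inside = box[dist <= radius]
    out[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    if brain_mask is not None:
        out &= brain_mask.data
    if not out.any():
        logger.warning("sphere at %s (r=%g mm) has no in-mask voxels", center, radius)
    return out


def make_coactivation_seed(
    study_id: str,
    group: str,
    foci,
    radius: float,
    grid: VolumeGrid,
    brain_mask: BrainMask,
) -> CoactivationSeed:
    """Union of per-focus spheres for one study (all foci must be MNI).

    Raises :class:`EmptySeedError` if every sphere is empty after masking.
    """
    foci = list(foci)
    if not foci:
        raise ValueError(f"study {study_id}: no foci")
    union = np.zeros(grid.shape, dtype=bool)
    for f in foci:
        if getattr(f, "space", "MNI") != "MNI":
            raise ValueError(f"study {study_id}: focus not in MNI space (run normalize_to_mni first)")
        union |= make_sphere(f.xyz, radius, grid, brain_mask)
    if not union.any():
        raise EmptySeedError(
            f"study {study_id}: all {len(foci)} sphere(s) are empty after brain-mask intersection"
        )
    vol = ScalarVolume(grid=grid, data=union.astype(float), kind="binary")
    return CoactivationSeed(study_id=study_id, group=group, mask=vol)


def _seed_column_indices(seed: CoactivationSeed, mask: BrainMask) -> np.ndarray:
    """Columns of the T x V matrix belonging to the seed's in-mask voxels."""
    check_same_grid(seed.grid, mask.grid, "seed and brain mask")
    seed_flat = np.flatnonzero(seed.mask.data.astype(bool).ravel() & mask.data.ravel())
    if seed_flat.size == 0:
        raise EmptySeedError(f"study {seed.study_id}: seed has no in-mask voxels")
    cols = np.searchsorted(mask.flat_indices, seed_flat)
    return cols


def seed_mean_timeseries(p: ParticipantTimeSeries, seed: CoactivationSeed) -> np.ndarray:
    """Unweighted mean over seed voxels' time series, one value per timepoint."""
    cols = _seed_column_indices(seed, p.mask)
    return p.data[:, cols].mean(axis=1)


def fisher_z_map(
    p: ParticipantTimeSeries,
    seed: CoactivationSeed,
    include_seed_voxels: bool = True,
    clip_eps: float = R_CLIP_EPS,
) -> FisherZMap:
    """Seed-to-voxel Pearson correlation, Fisher z-transformed.

    Per in-mask voxel v: r_v = corr(seed mean series, voxel series),
    z_v = atanh(r_v) with |r| clipped to 1 - ``clip_eps``.  Voxels whose
    series has zero variance get z = 0 (counted in ``n_zero_variance``).
    A zero-variance seed series yields an all-zero map with a warning.
    ``include_seed_voxels=False`` zeroes the seed's own voxels in the map.
    """
    s = seed_mean_timeseries(p, seed)
    s_c = s - s.mean()
    s_norm = float(np.linalg.norm(s_c))
    values = np.zeros(p.mask.n_voxels, dtype=float)
    n_zero = 0
    if s_norm == 0.0:
        logger.warning(
            "participant %s, study %s: seed mean series has zero variance; z map is all zero",
            p.participant_id, seed.study_id,
        )
    else:
        x_c = p.data - p.data.mean(axis=0)
        x_norm = np.linalg.norm(x_c, axis=0)
        degenerate = x_norm == 0.0
        n_zero = int(degenerate.sum())
        if n_zero:
            logger.warning(
                "participant %s, study %s: %d zero-variance voxel(s) set to z=0",
                p.participant_id, seed.study_id, n_zero,
            )
        safe_norm = np.where(degenerate, 1.0, x_norm)
        r = (s_c @ x_c) / (s_norm * safe_norm)
        r[degenerate] = 0.0
        r = np.clip(r, -(1.0 - clip_eps), 1.0 - clip_eps)
        values = np.arctanh(r)
    if not include_seed_voxels:
        values = values.copy()
        values[_seed_column_indices(seed, p.mask)] = 0.0
    return FisherZMap(
        participant_id=p.participant_id,
        study_id=seed.study_id,
        mask=p.mask,
        values=values,
        n_zero_variance=n_zero,
    )
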