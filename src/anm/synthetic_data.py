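"""Synthetic normative connectome and study-foci corpus with planted truth.

Stands in for a large resting-state reference sample (the real analysis
uses 1000 preprocessed participants): each participant's in-mask voxel
time series are white noise, except that every voxel of a planted
"network" shares that network's latent signal.  For voxels of network k
with signal SD ``sigma_s`` and noise SD ``sigma_n``, the expected pairwise
within-network correlation is

    rho = sigma_s**2 / (sigma_s**2 + sigma_n**2)

and cross-network correlations are zero in expectation.  Study foci are
drawn from their target network's voxel centers with bounded isotropic
jitter, so each study's coactivation seed lands inside a known network and
group-level recovery can be scored against exact ground truth.

Networks are axis-aligned voxel blocks: not anatomical, but exactly
enumerable, which is what parameter-recovery scoring needs.  Generation is
bit-reproducible: every participant and every study consumes its own RNG
substream keyed by (seed, role, index), so enlarging the sample never
perturbs earlier entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .foci import Focus, StudyFociTable
from .volumes import BrainMask, VolumeGrid
from .seeds_fc import ParticipantTimeSeries

_PARTICIPANT_STREAM = 11
_FOCI_STREAM = 22


@dataclass(frozen=True)
class NetworkSpec:
    """An axis-aligned block of voxels sharing one latent signal."""

    name: str
    corner: tuple[int, int, int]  # 0-based voxel index of the low corner
    size: tuple[int, int, int]
    signal_sd: float = 1.0

    def voxel_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        lo = np.asarray(self.corner)
        hi = lo + np.asarray(self.size)
        if np.any(lo < 0) or np.any(hi > np.asarray(shape)):
            raise ValueError(f"network {self.name!r} extends outside the grid")
        out = np.zeros(shape, dtype=bool)
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return out


@dataclass(frozen=True)
class StudySpec:
    """One simulated study: how many foci it reports and where they sit."""

    study_id: str
    n_foci: int = 3
    target: str | None = None  # network name, or None for pure-noise placement


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic connectome + foci corpus."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 4.0
    n_participants: int = 24
    n_timepoints: int = 120
    networks: tuple[NetworkSpec, ...] = ()
    noise_sd: float = 1.0
    studies: dict[str, tuple[StudySpec, ...]] = field(default_factory=dict)
    foci_jitter_mm: float = 2.0
    mask_style: str = "ellipsoid"  # or "full"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or any(n.signal_sd < 0 for n in self.networks):
            raise ValueError("signal and noise SDs must be >= 0")
        if self.mask_style not in ("ellipsoid", "full"):
            raise ValueError("mask_style must be 'ellipsoid' or 'full'")
        names = [n.name for n in self.networks]
        if len(set(names)) != len(names):
            raise ValueError("network names must be unique")
        # pairwise disjointness
        total = np.zeros(self.shape, dtype=int)
        for n in self.networks:
            total += n.voxel_mask(self.shape)
        if np.any(total > 1):
            raise ValueError("networks must be pairwise disjoint")
        for group, studies in self.studies.items():
            ids = [s.study_id for s in studies]
            if len(set(ids)) != len(ids):
                raise ValueError(f"group {group}: duplicate study ids")
            for s in studies:
                if s.target is not None and s.target not in names:
                    raise ValueError(f"study {s.study_id}: unknown target network {s.target!r}")

    @property
    def expected_within_network_r(self) -> dict[str, float]:
        """Closed-form rho = sigma_s^2 / (sigma_s^2 + sigma_n^2) per network."""
        out = {}
        for n in self.networks:
            denom = n.signal_sd**2 + self.noise_sd**2
            out[n.name] = n.signal_sd**2 / denom if denom > 0 else 0.0
        return out

    def make_grid(self) -> VolumeGrid:
        """Isotropic RAS+ grid centred on the world origin."""
        v = float(self.voxel_size_mm)
        origin = -v * (np.asarray(self.shape) - 1) / 2.0
        affine = np.diag([v, v, v, 1.0])
        affine[:3, 3] = origin
        return VolumeGrid(shape=self.shape, affine=affine)

    def make_mask(self) -> BrainMask:
        grid = self.make_grid()
        if self.mask_style == "full":
            data = np.ones(self.shape, dtype=bool)
        else:
            c = (np.asarray(self.shape) - 1) / 2.0
            idx = np.indices(self.shape)
            norm2 = sum(((idx[a] - c[a]) / (c[a] + 0.5)) ** 2 for a in range(3))
            data = norm2 <= 1.0
        for n in self.networks:
            if not np.all(data[n.voxel_mask(self.shape)]):
                raise ValueError(f"network {n.name!r} is not fully inside the brain mask")
        return BrainMask(grid=grid, data=data)


@dataclass
class GroundTruth:
    """Planted-network masks and per-group expected retained masks."""

    network_masks: dict[str, np.ndarray]
    expected_retained: dict[str, np.ndarray]
    grid: VolumeGrid
    mask: BrainMask


def simulate_connectome(spec: SyntheticSpec) -> tuple[list[ParticipantTimeSeries], BrainMask]:
    """Generate all participants' in-mask time series.

    Per participant: each network k draws an independent latent series
    (T standard normals x signal_sd); a voxel's series is its network's
    latent (if any) plus independent noise x noise_sd.
    """
    mask = spec.make_mask()
    grid = mask.grid
    mask_flat = mask.flat_indices
    # column index of each network's voxels in the T x V matrix
    net_cols = {
        n.name: np.searchsorted(mask_flat, np.flatnonzero(n.voxel_mask(spec.shape).ravel()))
        for n in spec.networks
    }
    participants = []
    for i in range(spec.n_participants):
        rng = np.random.default_rng([spec.rng_seed, _PARTICIPANT_STREAM, i])
        data = rng.standard_normal((spec.n_timepoints, mask.n_voxels)) * spec.noise_sd
        for n in spec.networks:
            latent = rng.standard_normal(spec.n_timepoints) * n.signal_sd
            data[:, net_cols[n.name]] += latent[:, None]
        participants.append(
            ParticipantTimeSeries(
                participant_id=f"sub-{i + 1:04d}", grid=grid, mask=mask, data=data
            )
        )
    return participants, mask


def simulate_foci(spec: SyntheticSpec) -> StudyFociTable:
    """Draw each study's peak coordinates from its target network.

    Foci are distinct voxel centers of the target network (world mm) plus
    isotropic jitter uniform in a ball of radius ``foci_jitter_mm``.  A
    jittered point whose nearest voxel falls outside the brain mask is
    clamped back to its unjittered voxel center.  Studies with no target
    draw from non-network in-mask voxels.
    """
    mask = spec.make_mask()
    grid = mask.grid
    net_masks = {n.name: n.voxel_mask(spec.shape) & mask.data for n in spec.networks}
    any_net = np.zeros(spec.shape, dtype=bool)
    for m in net_masks.values():
        any_net |= m
    background = mask.data & ~any_net

    entries: list[Focus] = []
    for gi, group in enumerate(sorted(spec.studies)):
        for si, study in enumerate(spec.studies[group]):
            rng = np.random.default_rng([spec.rng_seed, _FOCI_STREAM, gi, si])
            pool = net_masks[study.target] if study.target is not None else background
            ijk_pool = np.argwhere(pool)
            if len(ijk_pool) < study.n_foci:
                raise ValueError(
                    f"study {study.study_id}: target has {len(ijk_pool)} voxels, "
                    f"fewer than n_foci={study.n_foci}"
                )
            chosen = ijk_pool[rng.choice(len(ijk_pool), size=study.n_foci, replace=False)]
            centers = grid.voxel_to_world(chosen)
            for center in centers:
                point = center
                if spec.foci_jitter_mm > 0:
                    direction = rng.standard_normal(3)
                    norm = np.linalg.norm(direction)
                    direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
                    r = spec.foci_jitter_mm * rng.random() ** (1.0 / 3.0)
                    cand = center + r * direction
                    near = grid.world_to_nearest_voxel(cand)
                    if grid.contains_voxel(near) and mask.data[tuple(near)]:
                        point = cand
                entries.append(
                    Focus(
                        study_id=study.study_id,
                        group=group,
                        x=float(point[0]),
                        y=float(point[1]),
                        z=float(point[2]),
                        space="MNI",
                    )
                )
    return StudyFociTable(entries=tuple(entries))


def ground_truth(spec: SyntheticSpec, overlap_fraction: float = 0.60) -> GroundTruth:
    """Expected retained mask per group under the strict overlap rule.

    A planted network is expected in a group's map iff the fraction of that
    group's studies targeting it strictly exceeds ``overlap_fraction``.
    """
    mask = spec.make_mask()
    net_masks = {n.name: n.voxel_mask(spec.shape) & mask.data for n in spec.networks}
    expected: dict[str, np.ndarray] = {}
    for group, studies in spec.studies.items():
        out = np.zeros(spec.shape, dtype=bool)
        n_studies = len(studies)
        for name, net_mask in net_masks.items():
            n_target = sum(1 for s in studies if s.target == name)
            if n_studies and n_target / n_studies > overlap_fraction:
                out |= net_mask
        expected[group] = out
    return GroundTruth(
        network_masks=net_masks, expected_retained=expected, grid=mask.grid, mask=mask
    )


def spec_to_dict(spec: SyntheticSpec) -> dict:
    """Plain-dict form of a spec, suitable for YAML/JSON round-tripping."""
    return {
        "shape": list(spec.shape),
        "voxel_size_mm": spec.voxel_size_mm,
        "n_participants": spec.n_participants,
        "n_timepoints": spec.n_timepoints,
        "networks": [
            {"name": n.name, "corner": list(n.corner), "size": list(n.size),
             "signal_sd": n.signal_sd}
            for n in spec.networks
        ],
        "noise_sd": spec.noise_sd,
        "studies": {
            group: [
                {"study_id": s.study_id, "n_foci": s.n_foci, "target": s.target}
                for s in studies
            ]
            for group, studies in spec.studies.items()
        },
        "foci_jitter_mm": spec.foci_jitter_mm,
        "mask_style": spec.mask_style,
        "rng_seed": spec.rng_seed,
    }


def spec_from_dict(d: dict) -> SyntheticSpec:
    """Inverse of :func:`spec_to_dict`."""
    return SyntheticSpec(
        shape=tuple(d["shape"]),
        voxel_size_mm=float(d["voxel_size_mm"]),
        n_participants=int(d["n_participants"]),
        n_timepoints=int(d["n_timepoints"]),
        networks=tuple(
            NetworkSpec(
                name=n["name"], corner=tuple(n["corner"]), size=tuple(n["size"]),
                signal_sd=float(n.get("signal_sd", 1.0)),
            )
            for n in d.get("networks", [])
        ),
        noise_sd=float(d.get("noise_sd", 1.0)),
        studies={
            group: tuple(
                StudySpec(
                    study_id=s["study_id"], n_foci=int(s.get("n_foci", 3)),
                    target=s.get("target"),
                )
                for s in studies
            )
            for group, studies in d.get("studies", {}).items()
        },
        foci_jitter_mm=float(d.get("foci_jitter_mm", 0.0)),
        mask_style=d.get("mask_style", "ellipsoid"),
        rng_seed=int(d.get("rng_seed", 0)),
    )


def default_acceptance_spec(rng_seed: int = 0) -> SyntheticSpec:
    """The reference synthetic scenario used throughout the test suite.

    24^3 grid at 4 mm, 24 participants, T = 120, three disjoint 4x4x4
    networks with signal_sd = noise_sd = 1 (within-network rho = 0.5), and
    18 three-focus studies per group: every NT study targets "dmn", every
    ASD study targets "limbic", and "control" is untargeted — so the
    expected NT-minus-ASD set-difference contrast is exactly the "dmn"
    block.
    """
    networks = (
        NetworkSpec(name="dmn", corner=(4, 10, 10), size=(4, 4, 4), signal_sd=1.0),
        NetworkSpec(name="limbic", corner=(16, 10, 10), size=(4, 4, 4), signal_sd=1.0),
        NetworkSpec(name="control", corner=(10, 16, 10), size=(4, 4, 4), signal_sd=1.0),
    )
    studies = {
        "NT": tuple(
            StudySpec(study_id=f"nt{j + 1:02d}", n_foci=3, target="dmn") for j in range(18)
        ),
        "ASD": tuple(
            StudySpec(study_id=f"asd{j + 1:02d}", n_foci=3, target="limbic") for j in range(18)
        ),
    }
    return SyntheticSpec(
        shape=(24, 24, 24),
        voxel_size_mm=4.0,
        n_participants=24,
        n_timepoints=120,
        networks=networks,
        noise_sd=1.0,
        studies=studies,
        foci_jitter_mm=2.0,
        mask_style="ellipsoid",
        rng_seed=rng_seed,
    )
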