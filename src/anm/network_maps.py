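"""Group-level activation-network maps: overlap branch, t branch, contrasts.

Two complementary group-level summaries are built from the per-study stacks
of participant-level Fisher z maps:

*Overlap map* — each study's z stack is reduced to a voxelwise one-sample t
map across connectome participants, binarized at a fixed critical t
(default 5.66, the Bonferroni-style threshold printed for a 285,903-voxel
mask), and the binary maps are summed; a voxel enters the group network iff
it is significantly connected to strictly more than ``overlap_fraction``
(default 60%) of the studies' coactivation seeds.  With 18 studies the
minimal retaining count is therefore 11.

*t map* — each study's z stack is averaged across participants into an
experiment-level mean Fisher z map; those E maps are compared against zero
with a voxelwise one-sample t-test (df = E - 1) and thresholded at the same
critical t.

Group contrasts default to the set difference of the two groups' retained
masks; voxelwise two-proportion and Welch two-sample-t modes are available
as inferential alternatives.  All operations are deterministic given their
inputs; zero-variance voxels yield t = 0 (never NaN) and are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.stats

from .seeds_fc import FisherZMap
from .volumes import BrainMask, ScalarVolume, VolumeGrid, check_same_grid, volume_from_vector

logger = logging.getLogger(__name__)

THRESHOLD_MODES = ("fixed_t", "alpha_derived")
CONTRAST_MODES = ("set_difference", "proportion_test", "two_sample_t")
SIMILARITY_OPERANDS = ("unthresholded", "binarized")


@dataclass(frozen=True)
class AnmConfig:
    """Tunable parameters of the activation-network-mapping pipeline.

    ``t_threshold`` defaults to the fixed 5.66 used at both statistical
    levels in the original analysis; ``threshold_mode='alpha_derived'``
    instead derives a df-consistent two-sided Student-t critical value from
    ``alpha`` (default 0.05 / mask voxel count, set at run time).
    ``overlap_fraction`` is strict: a voxel is retained iff
    count/E > overlap_fraction.
    """

    radius: float = 6.0
    t_threshold: float = 5.66
    alpha: float | None = None  # None -> 0.05 / n_mask_voxels at run time
    overlap_fraction: float = 0.60
    threshold_mode: str = "fixed_t"
    contrast_mode: str = "set_difference"
    similarity_operands: str = "unthresholded"
    include_seed_voxels: bool = True
    tal_transform: str = "lacadie"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie strictly between 0 and 1")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be > 0")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"threshold_mode must be one of {THRESHOLD_MODES}")
        if self.contrast_mode not in CONTRAST_MODES:
            raise ValueError(f"contrast_mode must be one of {CONTRAST_MODES}")
        if self.similarity_operands not in SIMILARITY_OPERANDS:
            raise ValueError(f"similarity_operands must be one of {SIMILARITY_OPERANDS}")
        if self.alpha is not None and not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly between 0 and 1")

    def effective_alpha(self, n_mask_voxels: int) -> float:
        """Voxelwise Bonferroni alpha: 0.05 over the in-mask voxel count."""
        return self.alpha if self.alpha is not None else 0.05 / n_mask_voxels

    def effective_threshold(self, df: int, n_mask_voxels: int) -> float:
        if self.threshold_mode == "fixed_t":
            return self.t_threshold
        return critical_t(self.effective_alpha(n_mask_voxels), df)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentZStack:
    """All participants' Fisher z maps for one study (= one experiment)."""

    study_id: str
    group: str
    mask: BrainMask
    zmat: np.ndarray  # n_participants x V, pipeline voxel ordering
    participant_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        zmat = np.asarray(self.zmat, dtype=float)
        if zmat.ndim != 2 or zmat.shape[1] != self.mask.n_voxels:
            raise ValueError("zmat must be n_participants x n_mask_voxels")
        if zmat.shape[0] < 3:
            raise ValueError(f"study {self.study_id}: need >= 3 participants, got {zmat.shape[0]}")
        self.zmat = zmat
        if self.participant_ids and len(self.participant_ids) != zmat.shape[0]:
            raise ValueError("participant_ids length mismatch")

    @classmethod
    def from_maps(cls, study_id: str, group: str, maps: list[FisherZMap]) -> "ExperimentZStack":
        if len(maps) < 3:
            raise ValueError(f"study {study_id}: need >= 3 participant maps")
        mask = maps[0].mask
        return cls(
            study_id=study_id,
            group=group,
            mask=mask,
            zmat=np.stack([m.values for m in maps]),
            participant_ids=tuple(m.participant_id for m in maps),
        )

    @property
    def n_participants(self) -> int:
        return int(self.zmat.shape[0])


@dataclass
class OverlapMap:
    """Group network by the binarized-overlap rule."""

    group: str
    count: ScalarVolume
    fraction: ScalarVolume
    retained: ScalarVolume  # binary
    n_experiments: int
    overlap_fraction: float

    @property
    def min_retaining_count(self) -> int:
        """Smallest per-voxel count that satisfies count/E > overlap_fraction."""
        return min_retaining_count(self.n_experiments, self.overlap_fraction)


@dataclass
class GroupTMap:
    """Group network by the one-sample t-test over experiment-level mean z maps."""

    group: str
    t: ScalarVolume
    thresholded: ScalarVolume  # binary
    df: int
    t_threshold: float
    n_zero_variance: int = 0


@dataclass
class ContrastResult:
    """Directional group differences for the overlap and t branches."""

    mode: str
    overlap_nt_minus_asd: ScalarVolume
    overlap_asd_minus_nt: ScalarVolume
    t_nt_minus_asd: ScalarVolume
    t_asd_minus_nt: ScalarVolume
    provenance: dict = field(default_factory=dict)


def min_retaining_count(n_experiments: int, overlap_fraction: float) -> int:
    """Smallest integer c with c / E strictly greater than the overlap fraction."""
    c = int(np.floor(overlap_fraction * n_experiments)) + 1
    # guard against floor landing exactly on the boundary (fraction * E integral)
    while c / n_experiments <= overlap_fraction:  # pragma: no cover - defensive
        c += 1
    return c


def _stack_values(volumes, mask: BrainMask) -> np.ndarray:
    """n x V matrix of in-mask values from ScalarVolumes or ready vectors."""
    rows = []
    for v in volumes:
        if isinstance(v, ScalarVolume):
            rows.append(v.values_in(mask))
        else:
            arr = np.asarray(v, dtype=float)
            if arr.shape == mask.grid.shape:
                rows.append(arr[mask.data])
            elif arr.shape == (mask.n_voxels,):
                rows.append(arr)
            else:
                raise ValueError(f"cannot interpret stack entry of shape {arr.shape}")
    return np.stack(rows)


def one_sample_t(volumes, mask: BrainMask) -> ScalarVolume:
    """Voxelwise one-sample t against zero: t = mean / (sd / sqrt(n)), sd with n-1.

    Zero-variance voxels (including all-zero stacks) get t = 0, with a
    logged count.  Requires n >= 3.
    """
    stack = _stack_values(volumes, mask)
    n = stack.shape[0]
    if n < 3:
        raise ValueError(f"one-sample t needs >= 3 maps, got {n}")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    n_zero = int(degenerate.sum())
    if n_zero:
        logger.info("one_sample_t: %d zero-variance voxel(s) set to t=0", n_zero)
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~degenerate)
    t[degenerate] = 0.0
    return volume_from_vector(t, mask, kind="t")


def binarize(t_vol: ScalarVolume, threshold: float, mask: BrainMask) -> ScalarVolume:
    """1 iff t > threshold (strict), restricted to the brain mask."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    check_same_grid(t_vol.grid, mask.grid)
    data = ((t_vol.data > threshold) & mask.data).astype(float)
    return ScalarVolume(grid=mask.grid, data=data, kind="binary")


def overlap_map(
    binary_maps,
    overlap_fraction: float,
    mask: BrainMask,
    group: str = "",
) -> OverlapMap:
    """Voxelwise count of binarized experiment maps; retain iff count/E > fraction."""
    stack = _stack_values(binary_maps, mask)
    if not np.all(np.isin(stack, (0.0, 1.0))):
        raise ValueError("overlap_map expects binary maps")
    n_exp = stack.shape[0]
    count = stack.sum(axis=0)
    fraction = count / n_exp
    retained = (fraction > overlap_fraction).astype(float)
    return OverlapMap(
        group=group,
        count=volume_from_vector(count, mask, kind="count"),
        fraction=volume_from_vector(fraction, mask, kind="fraction"),
        retained=volume_from_vector(retained, mask, kind="binary"),
        n_experiments=n_exp,
        overlap_fraction=overlap_fraction,
    )


def experiment_mean_z(stack: ExperimentZStack) -> ScalarVolume:
    """Voxelwise mean of the participant-level Fisher z maps of one experiment."""
    return volume_from_vector(stack.zmat.mean(axis=0), stack.mask, kind="mean_z")


def group_t_map(
    mean_z_volumes,
    config: AnmConfig,
    mask: BrainMask,
    group: str = "",
) -> GroupTMap:
    """One-sample t across E experiment-level mean z maps, thresholded."""
    mean_z_volumes = list(mean_z_volumes)
    n_exp = len(mean_z_volumes)
    if n_exp < 3:
        raise ValueError(f"group t map needs >= 3 experiments, got {n_exp}")
    t_vol = one_sample_t(mean_z_volumes, mask)
    df = n_exp - 1
    threshold = config.effective_threshold(df, mask.n_voxels)
    n_zero = int(np.sum((t_vol.data == 0.0) & mask.data))
    return GroupTMap(
        group=group,
        t=t_vol,
        thresholded=binarize(t_vol, threshold, mask),
        df=df,
        t_threshold=threshold,
        n_zero_variance=n_zero,
    )


def build_group_maps(
    stacks: list[ExperimentZStack],
    config: AnmConfig,
    mask: BrainMask,
    group: str = "",
) -> tuple[OverlapMap, GroupTMap]:
    """Run both group-level branches over one group's per-study z stacks.

    Overlap branch: per study, one-sample t across participants, binarized
    at the experiment-level critical t, then the strict-majority overlap
    rule.  t branch: per-study mean z maps, one-sample t across studies.
    """
    if len(stacks) < 3:
        raise ValueError(f"group {group!r}: need >= 3 experiments, got {len(stacks)}")
    for s in stacks:
        check_same_grid(s.mask.grid, mask.grid, f"stack {s.study_id} and pipeline mask")
    rosters = {tuple(s.participant_ids) for s in stacks if s.participant_ids}
    if len(rosters) > 1:
        raise ValueError(f"group {group!r}: experiments use different participant rosters")

    binary_maps = []
    mean_maps = []
    for s in stacks:
        t_exp = one_sample_t(s.zmat, mask)
        thr = config.effective_threshold(s.n_participants - 1, mask.n_voxels)
        binary_maps.append(binarize(t_exp, thr, mask))
        mean_maps.append(experiment_mean_z(s))
    ov = overlap_map(binary_maps, config.overlap_fraction, mask, group=group)
    tm = group_t_map(mean_maps, config, mask, group=group)
    logger.info(
        "group %s: E=%d, overlap retains %d voxel(s) (min count %d), t map retains %d voxel(s)",
        group, len(stacks), int(ov.retained.data.sum()), ov.min_retaining_count,
        int(tm.thresholded.data.sum()),
    )
    return ov, tm


def _binary(data: np.ndarray, mask: BrainMask) -> ScalarVolume:
    return ScalarVolume(grid=mask.grid, data=(data & mask.data).astype(float), kind="contrast")


def contrast_maps(
    nt: tuple[OverlapMap, GroupTMap, list[ExperimentZStack]],
    asd: tuple[OverlapMap, GroupTMap, list[ExperimentZStack]],
    config: AnmConfig,
    mask: BrainMask,
) -> ContrastResult:
    """Directional NT-vs-ASD differences for both branches.

    ``set_difference`` (default): A-and-not-B of the retained/thresholded
    masks.  ``proportion_test``: voxelwise two-proportion z on overlap
    counts at the Bonferroni alpha.  ``two_sample_t``: voxelwise Welch t
    across the two groups' experiment-level mean z maps at the configured
    critical t.
    """
    nt_ov, nt_tm, nt_stacks = nt
    asd_ov, asd_tm, asd_stacks = asd
    mode = config.contrast_mode
    prov = {"mode": mode, "overlap_fraction": config.overlap_fraction}

    if mode == "set_difference":
        nt_ret = nt_ov.retained.data.astype(bool)
        asd_ret = asd_ov.retained.data.astype(bool)
        nt_thr = nt_tm.thresholded.data.astype(bool)
        asd_thr = asd_tm.thresholded.data.astype(bool)
        return ContrastResult(
            mode=mode,
            overlap_nt_minus_asd=_binary(nt_ret & ~asd_ret, mask),
            overlap_asd_minus_nt=_binary(asd_ret & ~nt_ret, mask),
            t_nt_minus_asd=_binary(nt_thr & ~asd_thr, mask),
            t_asd_minus_nt=_binary(asd_thr & ~nt_thr, mask),
            provenance=prov,
        )

    if mode == "proportion_test":
        alpha = config.effective_alpha(mask.n_voxels)
        z_crit = float(scipy.stats.norm.isf(alpha / 2.0))
        c1 = nt_ov.count.values_in(mask)
        c2 = asd_ov.count.values_in(mask)
        e1, e2 = nt_ov.n_experiments, asd_ov.n_experiments
        p1, p2 = c1 / e1, c2 / e2
        pooled = (c1 + c2) / (e1 + e2)
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / e1 + 1.0 / e2))
        z = np.zeros_like(p1)
        np.divide(p1 - p2, se, out=z, where=se > 0)
        prov.update(alpha=alpha, z_critical=z_crit)
        return ContrastResult(
            mode=mode,
            overlap_nt_minus_asd=volume_from_vector((z > z_crit).astype(float), mask, "contrast"),
            overlap_asd_minus_nt=volume_from_vector((z < -z_crit).astype(float), mask, "contrast"),
            t_nt_minus_asd=volume_from_vector(np.where(z > z_crit, z, 0.0), mask, "contrast"),
            t_asd_minus_nt=volume_from_vector(np.where(z < -z_crit, -z, 0.0), mask, "contrast"),
            provenance=prov,
        )

    # two_sample_t: Welch t across experiment-level mean z maps
    nt_means = np.stack([s.zmat.mean(axis=0) for s in nt_stacks])
    asd_means = np.stack([s.zmat.mean(axis=0) for s in asd_stacks])
    t_stat, _ = scipy.stats.ttest_ind(nt_means, asd_means, axis=0, equal_var=False)
    t_stat = np.nan_to_num(t_stat, nan=0.0)
    thr = config.t_threshold
    prov.update(t_threshold=thr)
    return ContrastResult(
        mode=mode,
        overlap_nt_minus_asd=volume_from_vector((t_stat > thr).astype(float), mask, "contrast"),
        overlap_asd_minus_nt=volume_from_vector((t_stat < -thr).astype(float), mask, "contrast"),
        t_nt_minus_asd=volume_from_vector(np.where(t_stat > thr, t_stat, 0.0), mask, "contrast"),
        t_asd_minus_nt=volume_from_vector(np.where(t_stat < -thr, -t_stat, 0.0), mask, "contrast"),
        provenance=prov,
    )


def map_similarity(a: ScalarVolume, b: ScalarVolume, mask: BrainMask) -> float:
    """Pearson correlation between two maps over in-mask voxels."""
    check_same_grid(a.grid, b.grid)
    va = a.values_in(mask)
    vb = b.values_in(mask)
    if va.size < 2:
        raise ValueError("need >= 2 in-mask voxels")
    va_c = va - va.mean()
    vb_c = vb - vb.mean()
    na, nb = np.linalg.norm(va_c), np.linalg.norm(vb_c)
    if na == 0.0 or nb == 0.0:
        raise ValueError("map similarity undefined: one operand has zero variance in-mask")
    return float(va_c @ vb_c / (na * nb))


def critical_t(alpha: float, df: int) -> float:
    """Two-sided Student-t critical value: upper-tail alpha/2 quantile at df."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(scipy.stats.t.isf(alpha / 2.0, df))
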