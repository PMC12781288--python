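"""End-to-end orchestration of a full activation-network-mapping run.

``run_group`` executes one group's branch of the pipeline (normalize foci
-> coactivation seeds -> participant Fisher z maps -> overlap and t maps);
``run_compare`` contrasts the two groups and computes each group's
overlap-vs-t map similarity.  Every run emits a :class:`RunManifest`
recording the configuration snapshot, per-stage counts, warnings, and
output paths, so results are auditable and byte-reproducible.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .foci import StudyFociTable, normalize_to_mni
from .network_maps import (
    AnmConfig,
    ContrastResult,
    ExperimentZStack,
    GroupTMap,
    OverlapMap,
    build_group_maps,
    contrast_maps,
    map_similarity,
)
from .seeds_fc import fisher_z_map, make_coactivation_seed
from .volumes import BrainMask, ScalarVolume, write_volume

logger = logging.getLogger(__name__)


def config_hash(config: AnmConfig) -> str:
    """Stable hash of the configuration (canonical JSON, sorted keys)."""
    payload = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record for one pipeline stage."""

    stage: str
    config: dict
    config_hash: str
    software_version: str
    counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


@dataclass
class GroupResult:
    group: str
    overlap: OverlapMap
    tmap: GroupTMap
    stacks: list[ExperimentZStack]
    seeds: dict[str, int]  # study_id -> seed voxel count
    manifest: RunManifest


@dataclass
class CompareResult:
    contrast: ContrastResult
    similarity: dict[str, float]  # group -> overlap-vs-t Pearson r
    manifest: RunManifest


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and entity."""


def run_group(
    table: StudyFociTable,
    participants,
    config: AnmConfig,
    mask: BrainMask,
    group: str,
    out_dir: str | Path | None = None,
) -> GroupResult:
    """Run the full per-group pipeline from foci to group network maps.

    ``participants`` is the shared connectome roster (identical for every
    study).  With fewer than 3 studies in the group this raises before any
    heavy computation.  When ``out_dir`` is given, all group volumes and a
    JSON manifest are written there.
    """
    table = normalize_to_mni(table.subset(group), method=config.tal_transform)
    studies = table.studies(group)
    if len(studies) < 3:
        raise PipelineError(
            f"stage=seeds group={group}: too few experiments ({len(studies)}; need >= 3)"
        )
    participants = list(participants)
    warnings: list[str] = []

    seeds = {}
    for study_id, foci in studies.items():
        try:
            seeds[study_id] = make_coactivation_seed(
                study_id, group, foci, config.radius, mask.grid, mask
            )
        except Exception as exc:
            raise PipelineError(f"stage=seeds study={study_id}: {exc}") from exc

    stacks = []
    for study_id, seed in seeds.items():
        maps = []
        for p in participants:
            try:
                maps.append(
                    fisher_z_map(p, seed, include_seed_voxels=config.include_seed_voxels)
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage=fisher_z study={study_id} participant={p.participant_id}: {exc}"
                ) from exc
        n_zero = sum(m.n_zero_variance for m in maps)
        if n_zero:
            warnings.append(f"study {study_id}: {n_zero} zero-variance voxel instances")
        stacks.append(ExperimentZStack.from_maps(study_id, group, maps))

    overlap, tmap = build_group_maps(stacks, config, mask, group=group)

    manifest = RunManifest(
        stage=f"group:{group}",
        config=config.to_dict(),
        config_hash=config_hash(config),
        software_version=__version__,
        counts={
            "n_studies": len(studies),
            "n_participants": len(participants),
            "n_mask_voxels": mask.n_voxels,
            "seed_voxels": {sid: s.n_voxels for sid, s in seeds.items()},
            "overlap_retained_voxels": int(overlap.retained.data.sum()),
            "overlap_min_retaining_count": overlap.min_retaining_count,
            "tmap_retained_voxels": int(tmap.thresholded.data.sum()),
            "tmap_df": tmap.df,
            "tmap_threshold": tmap.t_threshold,
        },
        warnings=warnings,
    )
    result = GroupResult(
        group=group,
        overlap=overlap,
        tmap=tmap,
        stacks=stacks,
        seeds={sid: s.n_voxels for sid, s in seeds.items()},
        manifest=manifest,
    )
    if out_dir is not None:
        _write_group_outputs(result, seeds, out_dir)
    return result


def _write_group_outputs(result: GroupResult, seeds, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = result.group.lower()
    volumes = {
        f"{g}_overlap_count.nii.gz": result.overlap.count,
        f"{g}_overlap_fraction.nii.gz": result.overlap.fraction,
        f"{g}_overlap_retained.nii.gz": result.overlap.retained,
        f"{g}_tmap.nii.gz": result.tmap.t,
        f"{g}_tmap_thresholded.nii.gz": result.tmap.thresholded,
    }
    for sid, seed in seeds.items():
        volumes[f"{g}_seed_{sid}.nii.gz"] = seed.mask
    for name, vol in volumes.items():
        write_volume(vol, out / name)
        result.manifest.outputs.append(str(out / name))
    result.manifest.write(out / f"{g}_manifest.json")


def run_compare(
    nt: GroupResult,
    asd: GroupResult,
    config: AnmConfig,
    mask: BrainMask,
    out_dir: str | Path | None = None,
) -> CompareResult:
    """Contrast the two groups and compute per-group overlap-vs-t similarity."""
    for r in (nt, asd):
        if r.manifest.config_hash != config_hash(config):
            raise PipelineError(
                f"stage=compare group={r.group}: result produced under a different config"
            )
    contrast = contrast_maps(
        (nt.overlap, nt.tmap, nt.stacks),
        (asd.overlap, asd.tmap, asd.stacks),
        config,
        mask,
    )
    similarity = {}
    for r in (nt, asd):
        if config.similarity_operands == "binarized":
            a, b = r.overlap.retained, r.tmap.thresholded
        else:
            a, b = r.overlap.fraction, r.tmap.t
        similarity[r.group] = map_similarity(a, b, mask)

    manifest = RunManifest(
        stage="compare",
        config=config.to_dict(),
        config_hash=config_hash(config),
        software_version=__version__,
        counts={
            "contrast_mode": config.contrast_mode,
            "similarity_operands": config.similarity_operands,
            "similarity": {k: float(v) for k, v in similarity.items()},
            "overlap_nt_minus_asd_voxels": int(np.count_nonzero(contrast.overlap_nt_minus_asd.data)),
            "overlap_asd_minus_nt_voxels": int(np.count_nonzero(contrast.overlap_asd_minus_nt.data)),
            "t_nt_minus_asd_voxels": int(np.count_nonzero(contrast.t_nt_minus_asd.data)),
            "t_asd_minus_nt_voxels": int(np.count_nonzero(contrast.t_asd_minus_nt.data)),
        },
    )
    result = CompareResult(contrast=contrast, similarity=similarity, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, vol in {
            "contrast_overlap_nt_minus_asd.nii.gz": contrast.overlap_nt_minus_asd,
            "contrast_overlap_asd_minus_nt.nii.gz": contrast.overlap_asd_minus_nt,
            "contrast_t_nt_minus_asd.nii.gz": contrast.t_nt_minus_asd,
            "contrast_t_asd_minus_nt.nii.gz": contrast.t_asd_minus_nt,
        }.items():
            write_volume(vol, out / name)
            manifest.outputs.append(str(out / name))
        manifest.write(out / "compare_manifest.json")
    return result


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of two binary arrays (1.0 if both empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)


def sensitivity_fdp(detected: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of a detection mask vs truth."""
    detected = np.asarray(detected).astype(bool)
    truth = np.asarray(truth).astype(bool)
    tp = np.logical_and(detected, truth).sum()
    sens = tp / truth.sum() if truth.sum() else 1.0
    fdp = (detected.sum() - tp) / detected.sum() if detected.sum() else 0.0
    return float(sens), float(fdp)
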