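"""Study activation-peak tables and Talairach<->MNI coordinate conversion.

Every included study contributes a set of reported activation peaks
("foci") tagged with its group (autistic ``ASD`` or neurotypical ``NT``)
and the stereotaxic space the study reported in.  Before seeding, all
Talairach coordinates are converted to MNI.  Two published transforms are
available:

``lacadie``
    The BioImage-Suite MNI->Talairach affine (Lacadie et al.); the
    TAL->MNI direction is its exact matrix inverse, so the round trip is
    exact to machine precision.
``brett``
    The classic piecewise-affine transform with separate matrices above
    and below the AC plane (z >= 0 / z < 0).  Piecewise inverses are
    applied per branch; the round trip is exact within a branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("ASD", "NT")
SPACES = ("MNI", "TAL")

_GROUP_ALIASES = {
    "asd": "ASD", "autism": "ASD", "autistic": "ASD", "aut": "ASD",
    "nt": "NT", "neurotypical": "NT", "control": "NT", "td": "NT", "hc": "NT",
}
_SPACE_ALIASES = {
    "mni": "MNI", "mni152": "MNI", "mni305": "MNI",
    "tal": "TAL", "talairach": "TAL", "tlrc": "TAL",
}

COORD_SANITY_MM = 200.0

# MNI -> Talairach affine, BioImage-Suite coefficients (Lacadie et al.).
LACADIE_MNI_TO_TAL = np.array(
    [
        [0.9357, 0.0029, -0.0072, -1.0423],
        [-0.0065, 0.9396, -0.0726, -1.3940],
        [0.0103, 0.0752, 0.8967, 3.6475],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
LACADIE_TAL_TO_MNI = np.linalg.inv(LACADIE_MNI_TO_TAL)

# Brett piecewise MNI -> Talairach (rows are 3x4 affines; branch on z).
_BRETT_MNI_TO_TAL_ZPOS = np.array(
    [
        [0.9900, 0.0, 0.0, 0.0],
        [0.0, 0.9688, 0.0460, 0.0],
        [0.0, -0.0485, 0.9189, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
_BRETT_MNI_TO_TAL_ZNEG = np.array(
    [
        [0.9900, 0.0, 0.0, 0.0],
        [0.0, 0.9688, 0.0420, 0.0],
        [0.0, -0.0485, 0.8390, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

TRANSFORMS = ("lacadie", "brett")


class FociValidationError(ValueError):
    """A foci table failed validation; the message names row and column."""


@dataclass(frozen=True)
class Focus:
    """One reported activation peak."""

    study_id: str
    group: str
    x: float
    y: float
    z: float
    space: str = "MNI"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FociValidationError(f"unknown group {self.group!r} (expected one of {GROUPS})")
        if self.space not in SPACES:
            raise FociValidationError(f"unknown space {self.space!r} (expected one of {SPACES})")
        xyz = np.array([self.x, self.y, self.z], dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise FociValidationError(f"study {self.study_id}: non-finite coordinate {xyz}")
        if np.any(np.abs(xyz) >= COORD_SANITY_MM):
            raise FociValidationError(
                f"study {self.study_id}: coordinate {xyz} exceeds +/-{COORD_SANITY_MM:g} mm sanity bound"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class StudyFociTable:
    """All foci of a corpus, grouped by study and diagnostic group."""

    entries: tuple[Focus, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise FociValidationError("foci table is empty")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def study_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for f in self.entries:
            seen.setdefault(f.study_id, None)
        return tuple(seen)

    def studies(self, group: str | None = None) -> dict[str, list[Focus]]:
        """Map study_id -> foci, optionally restricted to one group."""
        out: dict[str, list[Focus]] = {}
        for f in self.entries:
            if group is None or f.group == group:
                out.setdefault(f.study_id, []).append(f)
        return out

    def subset(self, group: str) -> "StudyFociTable":
        kept = [f for f in self.entries if f.group == group]
        if not kept:
            raise FociValidationError(f"no foci for group {group!r}")
        return StudyFociTable(entries=tuple(kept))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"study_id": f.study_id, "group": f.group, "x": f.x, "y": f.y,
                 "z": f.z, "space": f.space}
                for f in self.entries
            ]
        )


def _normalize_token(raw: str, aliases: dict[str, str], column: str, row: int) -> str:
    token = aliases.get(str(raw).strip().lower())
    if token is None:
        raise FociValidationError(f"row {row}: unknown {column} token {raw!r}")
    return token


def read_foci(path: str | Path) -> StudyFociTable:
    """Read and validate a foci TSV with header study_id, group, x, y, z, space.

    Exact duplicate rows are dropped with a logged warning.  Any malformed
    cell raises :class:`FociValidationError` naming the offending row and
    column (rows are counted from 1, excluding the header).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["study_id", "group", "x", "y", "z", "space"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FociValidationError(f"{path}: missing column(s) {missing}")
    n_raw = len(df)
    df = df.drop_duplicates()
    if len(df) < n_raw:
        logger.warning("%s: dropped %d duplicate foci row(s)", path, n_raw - len(df))

    entries: list[Focus] = []
    for pos, (_, rec) in enumerate(df.iterrows(), start=1):
        coords = {}
        for col in ("x", "y", "z"):
            try:
                coords[col] = float(rec[col])
            except (TypeError, ValueError):
                raise FociValidationError(
                    f"{path}: row {pos}, column {col!r}: unparseable coordinate {rec[col]!r}"
                ) from None
        entries.append(
            Focus(
                study_id=str(rec["study_id"]).strip(),
                group=_normalize_token(rec["group"], _GROUP_ALIASES, "group", pos),
                space=_normalize_token(rec["space"], _SPACE_ALIASES, "space", pos),
                **coords,
            )
        )
    return StudyFociTable(entries=tuple(entries))


def write_foci(table: StudyFociTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def _apply_affine(mat: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ mat[:3, :3].T + mat[:3, 3]


def mni_to_tal(xyz, method: str = "lacadie") -> np.ndarray:
    """Convert MNI mm coordinates (shape (..., 3)) to Talairach mm."""
    xyz = np.asarray(xyz, dtype=float)
    if method == "lacadie":
        return _apply_affine(LACADIE_MNI_TO_TAL, xyz)
    if method == "brett":
        pos = _apply_affine(_BRETT_MNI_TO_TAL_ZPOS, xyz)
        neg = _apply_affine(_BRETT_MNI_TO_TAL_ZNEG, xyz)
        branch = (xyz[..., 2] >= 0)[..., None]
        return np.where(branch, pos, neg)
    raise ValueError(f"unknown transform {method!r}; expected one of {TRANSFORMS}")


def tal_to_mni(xyz, method: str = "lacadie") -> np.ndarray:
    """Convert Talairach mm coordinates (shape (..., 3)) to MNI mm."""
    xyz = np.asarray(xyz, dtype=float)
    if method == "lacadie":
        return _apply_affine(LACADIE_TAL_TO_MNI, xyz)
    if method == "brett":
        pos = _apply_affine(np.linalg.inv(_BRETT_MNI_TO_TAL_ZPOS), xyz)
        neg = _apply_affine(np.linalg.inv(_BRETT_MNI_TO_TAL_ZNEG), xyz)
        branch = (xyz[..., 2] >= 0)[..., None]
        return np.where(branch, pos, neg)
    raise ValueError(f"unknown transform {method!r}; expected one of {TRANSFORMS}")


def normalize_to_mni(table: StudyFociTable, method: str = "lacadie") -> StudyFociTable:
    """Convert every Talairach focus to MNI; MNI foci are untouched.

    Idempotent: a table that is already all-MNI is returned with
    bit-identical coordinates.
    """
    converted = 0
    entries: list[Focus] = []
    for f in table.entries:
        if f.space == "TAL":
            x, y, z = tal_to_mni(f.xyz, method=method)
            entries.append(replace(f, x=float(x), y=float(y), z=float(z), space="MNI"))
            converted += 1
        else:
            entries.append(f)
    if converted:
        logger.info("converted %d focus/foci from Talairach to MNI (%s)", converted, method)
    return StudyFociTable(entries=tuple(entries))
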