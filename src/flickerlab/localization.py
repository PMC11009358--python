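"""Electrode-contact anatomical label assignment.

A contact is labeled from a voxel label volume by the weighted
search-sphere rule: collect every voxel center within 5 mm of the contact,
drop white-matter voxels, weight each remaining voxel by 1/r (weight 1 at
r = 0), sum weights per label, and return the label with the greatest
total signal strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("flickerlab")

SEARCH_RADIUS_MM = 5.0
EXCLUDED_LABELS = frozenset({"cerebral-white-matter", "wm-hypointensities"})


@dataclass
class LabelVolume:
    """Integer voxel label grid with label names and a voxel->world affine."""

    labels: np.ndarray
    names: dict[int, str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, float)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if self.affine.shape != (4, 4) or np.isclose(
            np.linalg.det(self.affine[:3, :3]), 0
        ):
            raise ValueError("affine must be an invertible 4x4 matrix")

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def assign_anatomical_label(
    electrode_xyz: np.ndarray,
    volume: LabelVolume,
    radius: float = SEARCH_RADIUS_MM,
    excluded: frozenset[str] = EXCLUDED_LABELS,
) -> tuple[str | None, pd.DataFrame]:
    """Label one electrode contact from the surrounding voxel labels.

    Returns ``(label_name, score_table)``; the label is ``None`` when every
    in-sphere voxel carries an excluded (white-matter) label.  Ties go to
    the lexicographically smallest label id.
    """
    xyz = np.asarray(electrode_xyz, float).ravel()
    if xyz.shape != (3,):
        raise ValueError("electrode_xyz must be a 3-vector (world mm)")
    center_ijk = volume.world_to_voxel(xyz)[0]
    if np.any(center_ijk < -0.5) or np.any(
        center_ijk >= np.array(volume.labels.shape) - 0.5
    ):
        raise ValueError("electrode outside the label volume")

    # candidate voxel box in index space, then exact world-distance filter
    scale = np.linalg.norm(volume.affine[:3, :3], axis=0)
    half = np.ceil(radius / scale).astype(int) + 1
    lo = np.maximum(np.floor(center_ijk).astype(int) - half, 0)
    hi = np.minimum(
        np.floor(center_ijk).astype(int) + half + 1, volume.labels.shape
    )
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
    )
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = volume.voxel_to_world(ijk)
    r = np.linalg.norm(world - xyz, axis=1)
    inside = r <= radius
    ijk, r = ijk[inside], r[inside]
    labs = volume.labels[ijk[:, 0], ijk[:, 1], ijk[:, 2]]

    weights = np.where(r == 0, 1.0, 1.0 / np.maximum(r, 1e-12))
    scores: dict[int, float] = {}
    counts: dict[int, int] = {}
    for lab, w in zip(labs, weights):
        name = volume.names.get(int(lab), str(lab))
        if name in excluded:
            continue
        scores[int(lab)] = scores.get(int(lab), 0.0) + float(w)
        counts[int(lab)] = counts.get(int(lab), 0) + 1

    table = pd.DataFrame(
        dict(
            label_id=list(scores.keys()),
            label=[volume.names.get(l, str(l)) for l in scores],
            score=list(scores.values()),
            n_voxels=[counts[l] for l in scores],
        )
    ).sort_values(["score", "label_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    if table.empty:
        return None, table
    best = table.loc[table["score"] == table["score"].max()].sort_values(
        "label_id"
    )
    return str(best.iloc[0]["label"]), table
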