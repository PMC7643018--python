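"""ROI patch subdivision, patch propagation and patch-feature extraction.

Each ROI is split into ``k = max(1, round(size / scale))`` patches by 1-D
k-means — on voxel intensity for volume features, on vertex thickness for
surface features.  Clustering happens once, in template space; per-subject
patches come from propagating the template atlas through a correspondence
map (identity by default), never from re-clustering, so features stay
comparable across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from neurodiff.datamodel import FeatureSetSpec, FeatureTable

logger = logging.getLogger(__name__)


def n_patches_for(size: int, scale: int) -> int:
    """Target patch count for an ROI of ``size`` members at ``scale``."""
    return max(1, int(round(size / scale)))


@dataclass
class PatchAtlas:
    """Patch membership of every ROI at one (feature_type, scale).

    ``entries`` maps (roi_id, patch_idx) to a sorted array of member ids;
    patch indices are contiguous from 0 within each ROI and ordered by
    ascending cluster centre so the labelling is deterministic.
    """

    feature_type: str
    scale: int
    entries: dict = field(default_factory=dict)

    def rois(self) -> list[int]:
        return sorted({roi for roi, _ in self.entries})

    def n_patches(self, roi_id: int) -> int:
        return sum(1 for r, _ in self.entries if r == roi_id)

    @property
    def n_total_patches(self) -> int:
        return len(self.entries)

    def member_count(self, roi_id: int, patch_idx: int) -> int:
        return len(self.entries[(roi_id, patch_idx)])

    def patch_keys(self) -> list[tuple[int, int]]:
        return sorted(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_type": self.feature_type,
                "scale": self.scale,
                "roi_id": roi,
                "patch_idx": patch,
                "member_id": int(m),
            }
            for (roi, patch), members in sorted(self.entries.items())
            for m in members
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PatchAtlas":
        feature_type = df["feature_type"].iloc[0]
        scale = int(df["scale"].iloc[0])
        entries = {
            (int(roi), int(patch)): np.sort(g["member_id"].to_numpy(dtype=int))
            for (roi, patch), g in df.groupby(["roi_id", "patch_idx"])
        }
        return cls(feature_type, scale, entries)

    def __eq__(self, other):
        if not isinstance(other, PatchAtlas):
            return NotImplemented
        if (self.feature_type, self.scale) != (other.feature_type, other.scale):
            return False
        if set(self.entries) != set(other.entries):
            return False
        return all(
            np.array_equal(np.sort(self.entries[k]), np.sort(other.entries[k]))
            for k in self.entries
        )


@dataclass
class CorrespondenceMap:
    """Template-to-target id map (one-to-many allowed)."""

    mapping: Mapping[int, Sequence[int]] | None = None
    identity: bool = False

    def targets(self, member_id: int) -> list[int]:
        if self.identity:
            return [int(member_id)]
        if member_id not in self.mapping:
            raise KeyError(member_id)
        return [int(t) for t in self.mapping[member_id]]

    def compose(self, other: "CorrespondenceMap") -> "CorrespondenceMap":
        """``self`` then ``other`` (other ∘ self)."""
        if self.identity:
            return other
        if other.identity:
            return self
        out = {
            src: [t2 for t1 in targets for t2 in other.targets(t1)]
            for src, targets in self.mapping.items()
        }
        return CorrespondenceMap(out)

    def to_frame(self) -> pd.DataFrame:
        if self.identity:
            raise ValueError("identity map has no explicit rows")
        rows = [
            {"template_id": int(s), "target_id": int(t)}
            for s, targets in sorted(self.mapping.items())
            for t in targets
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CorrespondenceMap":
        mapping: dict[int, list[int]] = {}
        for s, t in zip(df["template_id"], df["target_id"]):
            mapping.setdefault(int(s), []).append(int(t))
        return cls(mapping)


def _cluster_1d(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    """1-D k-means labels, relabelled by ascending cluster centre."""
    if k == 1:
        return np.zeros(values.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(values.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]


def subdivide_roi_volume(
    members: Sequence[int], intensities: Sequence[float], scale: int, seed: int = 0
) -> dict[int, np.ndarray]:
    """Split one ROI's voxels into intensity-similarity patches.

    Returns patch_idx -> sorted member-id array.
    """
    members = np.asarray(members, dtype=int)
    intensities = np.asarray(intensities, dtype=float)
    if members.size == 0:
        raise ValueError("empty ROI")
    if intensities.shape[0] != members.shape[0]:
        raise ValueError("intensities length differs from members")
    k = n_patches_for(members.size, scale)
    labels = _cluster_1d(intensities, k, seed)
    return {p: np.sort(members[labels == p]) for p in range(k)}


def subdivide_roi_surface(
    vertex_ids: Sequence[int], thicknesses: Sequence[float], scale: int, seed: int = 0
) -> dict[int, np.ndarray]:
    """Split one cortical ROI's vertices into thickness-distance patches."""
    return subdivide_roi_volume(vertex_ids, thicknesses, scale, seed)


def build_volume_atlas(template, scale: int, seed: int = 0) -> PatchAtlas:
    """Patch every volume ROI of a template at one scale."""
    atlas = PatchAtlas("volume", scale)
    labels = template.label_volume.ravel()
    intensities = template.intensity_volume.ravel()
    for roi in np.unique(labels):
        if roi == 0:
            continue
        members = np.flatnonzero(labels == roi)
        patches = subdivide_roi_volume(
            members, intensities[members], scale, seed=seed + int(roi)
        )
        for p, m in patches.items():
            atlas.entries[(int(roi), p)] = m
    return atlas


def build_surface_atlas(template, scale: int, seed: int = 0) -> PatchAtlas:
    """Patch every cortical ROI's vertices at one scale."""
    atlas = PatchAtlas("thickness", scale)
    vt = template.vertex_table
    for roi, g in vt.groupby("roi_id"):
        patches = subdivide_roi_surface(
            g["vertex_id"].to_numpy(int),
            g["thickness"].to_numpy(float),
            scale,
            seed=seed + int(roi),
        )
        for p, m in patches.items():
            atlas.entries[(int(roi), p)] = m
    return atlas


def propagate(atlas: PatchAtlas, cmap: CorrespondenceMap) -> PatchAtlas:
    """Map template patch membership into a target space.

    Every template member must be covered by the map; unmapped members
    raise with the offending ids listed.
    """
    if cmap.identity:
        return PatchAtlas(
            atlas.feature_type,
            atlas.scale,
            {k: np.array(v, dtype=int, copy=True) for k, v in atlas.entries.items()},
        )
    unmapped = sorted(
        int(m)
        for members in atlas.entries.values()
        for m in members
        if int(m) not in cmap.mapping
    )
    if unmapped:
        raise ValueError(f"unmapped member ids: {unmapped[:20]}")
    out = {}
    for key, members in atlas.entries.items():
        targets = sorted({t for m in members for t in cmap.targets(int(m))})
        out[key] = np.array(targets, dtype=int)
    return PatchAtlas(atlas.feature_type, atlas.scale, out)


# -- feature extraction ----------------------------------------------------


@dataclass
class SubjectScan:
    """Per-scan input to feature extraction.

    ``thickness`` maps template vertex ids to this scan's thickness values;
    ``correspondence`` defaults to the identity map.
    """

    subject_id: str
    visit_id: str
    voxel_volume_mm3: float = 1.0
    thickness: Mapping[int, float] | None = None
    correspondence: CorrespondenceMap = field(
        default_factory=lambda: CorrespondenceMap(identity=True)
    )


CANONICAL_BLOCK_ORDER = (("volume", 500), ("volume", 1000), ("volume", 2000),
                         ("thickness", 500), ("thickness", 1000), ("thickness", 2000))


def extract_patch_features(
    template, atlases: Sequence[PatchAtlas], scans: Sequence[SubjectScan]
) -> FeatureTable:
    """Patch features for every scan: volume = member count x voxel volume,
    thickness = mean member thickness.  Empty propagated patches yield 0
    with a logged warning.
    """
    atlases = sorted(
        atlases, key=lambda a: CANONICAL_BLOCK_ORDER.index((a.feature_type, a.scale))
    )
    specs, columns = [], []
    for atlas in atlases:
        keys = atlas.patch_keys()
        specs.append(FeatureSetSpec(atlas.feature_type, atlas.scale, len(keys)))
        columns.extend(
            f"{atlas.feature_type}_{atlas.scale}_{roi}_{patch}" for roi, patch in keys
        )
    template_thickness = None
    if template is not None and getattr(template, "vertex_table", None) is not None:
        vt = template.vertex_table
        template_thickness = dict(
            zip(vt["vertex_id"].astype(int), vt["thickness"].astype(float))
        )

    rows = np.zeros((len(scans), len(columns)))
    for si, scan in enumerate(scans):
        col = 0
        for atlas in atlases:
            target = propagate(atlas, scan.correspondence)
            for key in atlas.patch_keys():
                members = target.entries[key]
                if members.size == 0:
                    logger.warning(
                        "empty patch %s for scan %s; feature set to 0",
                        key, scan.subject_id,
                    )
                    rows[si, col] = 0.0
                elif atlas.feature_type == "volume":
                    rows[si, col] = members.size * scan.voxel_volume_mm3
                else:
                    source = scan.thickness or template_thickness
                    if source is None:
                        raise ValueError(
                            f"no thickness data for scan {scan.subject_id}"
                        )
                    rows[si, col] = float(
                        np.mean([source[int(m)] for m in members])
                    )
                col += 1
    ids = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in scans],
            "visit_id": [s.visit_id for s in scans],
        }
    )
    return FeatureTable(ids, rows, columns, specs, kind="raw")
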