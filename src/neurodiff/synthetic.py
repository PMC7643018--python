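"""Synthetic templates and cohorts with known covariate and group effects.

The cohort generator produces feature tables following

    feature = baseline + sum(covariate_slope * covariate)
              + (group_shift + subject_effect + noise) * noise_sd

where group shifts are expressed in residual-SD units, so classifier
difficulty is a single effect-size knob, and all scans of one subject share
a subject-level random intercept (making subject-level CV splits matter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from neurodiff.datamodel import (
    Diagnosis,
    FeatureSetSpec,
    FeatureTable,
    FieldStrength,
    Sex,
    SubjectRecord,
    default_column_names,
    total_dimension,
)

logger = logging.getLogger(__name__)

GROUPS = ("NC", "AD", "FTD")


@dataclass
class SyntheticTemplate:
    """Label/intensity volumes plus a cortical vertex table."""

    label_volume: np.ndarray  # 3-D int, 0 = background
    intensity_volume: np.ndarray  # 3-D float
    vertex_table: pd.DataFrame  # vertex_id, x, y, z, thickness, roi_id
    voxel_size_mm: float = 1.0
    roi_intensity_modes: dict = field(default_factory=dict)  # roi -> mode means

    def roi_ids(self) -> list[int]:
        ids = np.unique(self.label_volume)
        return [int(r) for r in ids if r != 0]

    def roi_members(self, roi_id: int) -> np.ndarray:
        return np.flatnonzero(self.label_volume.ravel() == roi_id)


def generate_template(
    n_volume_rois: int = 5,
    n_cortical_rois: int = 4,
    roi_size_range: tuple[int, int] = (800, 1500),
    seed: int = 0,
    vertex_count_range: tuple[int, int] | None = None,
) -> SyntheticTemplate:
    """A deterministic synthetic template.

    ROI voxel counts are uniform on ``roi_size_range``; intensities within
    each ROI are a 1-3 mode Gaussian mixture (so k-means subdivision is
    non-degenerate); vertex thicknesses vary smoothly within each cortical
    ROI.
    """
    if n_volume_rois < 1 or n_cortical_rois < 1:
        raise ValueError("need at least one ROI of each kind")
    lo, hi = roi_size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad roi_size_range {roi_size_range}")
    rng = np.random.default_rng(seed)

    sizes = rng.integers(lo, hi + 1, size=n_volume_rois)
    total = int(sizes.sum())
    side = int(np.ceil((total / 0.8) ** (1.0 / 3.0)))  # ~20% background
    if side < 2:
        raise ValueError("infeasible volume dimensions")
    labels = np.zeros(side ** 3, dtype=int)
    intensity = np.zeros(side ** 3)
    modes_by_roi: dict[int, list[float]] = {}
    start = 0
    for roi in range(1, n_volume_rois + 1):
        size = int(sizes[roi - 1])
        members = np.arange(start, start + size)
        start += size
        labels[members] = roi
        n_modes = int(rng.integers(1, 4))
        base = rng.uniform(60.0, 140.0)
        means = [base + 35.0 * m for m in range(n_modes)]
        modes_by_roi[roi] = means
        assignment = rng.integers(0, n_modes, size=size)
        intensity[members] = rng.normal(
            np.take(means, assignment), 3.0
        )
    shape = (side, side, side)

    vlo, vhi = vertex_count_range or roi_size_range
    rows = []
    vid = 0
    for roi in range(1, n_cortical_rois + 1):
        n_vert = int(rng.integers(vlo, vhi + 1))
        base = rng.uniform(2.0, 3.2)
        cycles = rng.uniform(1.0, 3.0)
        idx = np.arange(n_vert)
        thickness = (
            base
            + 0.35 * np.sin(2.0 * np.pi * cycles * idx / n_vert)
            + rng.normal(0.0, 0.02, size=n_vert)
        )
        xyz = rng.uniform(0.0, 100.0, size=(n_vert, 3))
        for i in range(n_vert):
            rows.append(
                {
                    "vertex_id": vid,
                    "x": xyz[i, 0],
                    "y": xyz[i, 1],
                    "z": xyz[i, 2],
                    "thickness": thickness[i],
                    "roi_id": roi,
                }
            )
            vid += 1
    vertex_table = pd.DataFrame(rows)
    return SyntheticTemplate(
        labels.reshape(shape),
        intensity.reshape(shape),
        vertex_table,
        voxel_size_mm=1.0,
        roi_intensity_modes=modes_by_roi,
    )


def save_template(template: SyntheticTemplate, prefix: str) -> None:
    """Write label/intensity NIfTI volumes and the vertex CSV."""
    import nibabel as nib

    affine = np.diag([template.voxel_size_mm] * 3 + [1.0])
    nib.save(
        nib.Nifti1Image(template.label_volume.astype(np.int32), affine),
        f"{prefix}_labels.nii",
    )
    nib.save(
        nib.Nifti1Image(template.intensity_volume.astype(np.float32), affine),
        f"{prefix}_intensity.nii",
    )
    template.vertex_table.to_csv(f"{prefix}_vertices.csv", index=False)


def load_template(prefix: str) -> SyntheticTemplate:
    import nibabel as nib

    labels = np.asarray(nib.load(f"{prefix}_labels.nii").dataobj).astype(int)
    intensity = np.asarray(nib.load(f"{prefix}_intensity.nii").dataobj).astype(float)
    vertices = pd.read_csv(f"{prefix}_vertices.csv")
    return SyntheticTemplate(labels, intensity, vertices)


# -- cohorts ---------------------------------------------------------------


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``covariate_effects`` maps covariate name (age, sex, icv,
    field_strength) to a slope — scalar (applied to every feature) or a
    per-feature array.  ``group_effect_maps`` holds per-group mean shifts
    in residual-SD units over the concatenated feature axis.
    """

    n_per_group: Mapping[str, int]
    covariate_effects: Mapping[str, object] = field(default_factory=dict)
    group_effect_maps: Mapping[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0
    scans_per_subject: int = 1
    subject_sd: float = 0.0
    baseline: float = 1000.0

    def validate(self, n_features: int) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group counts must be >= 0")
        if not np.all(np.asarray(self.noise_sd) > 0):
            raise ValueError("noise_sd must be > 0")
        if self.scans_per_subject < 1:
            raise ValueError("scans_per_subject must be >= 1")
        for g, m in self.group_effect_maps.items():
            if np.asarray(m).shape != (n_features,):
                raise ValueError(
                    f"effect map for {g} has shape {np.asarray(m).shape}, "
                    f"expected ({n_features},)"
                )
        for cov in self.covariate_effects:
            if cov not in ("age", "sex", "icv", "field_strength"):
                raise ValueError(f"unknown covariate {cov!r}")


def make_disjoint_effect_maps(
    n_features: int, sparsity: float, effect_size: float, seed: int = 0
) -> dict[str, np.ndarray]:
    """AD/FTD effect maps on disjoint random feature supports (NC zero).

    A ``sparsity`` fraction of features carries signal, split evenly
    between AD and FTD, with random shift signs of magnitude
    ``effect_size``.
    """
    rng = np.random.default_rng(seed)
    n_signal = int(round(sparsity * n_features))
    support = rng.choice(n_features, size=n_signal, replace=False)
    half = n_signal // 2
    maps = {g: np.zeros(n_features) for g in GROUPS}
    signs = rng.choice([-1.0, 1.0], size=n_signal)
    maps["AD"][support[:half]] = effect_size * signs[:half]
    maps["FTD"][support[half:]] = effect_size * signs[half:]
    return maps


def make_overlapping_effect_maps(
    n_features: int,
    sparsity: float,
    effect_size: float,
    jaccard: float = 0.3,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """AD/FTD maps whose supports overlap with the given Jaccard index,
    emulating similar NC-vs-disease patterns with an AD/FTD discrepancy."""
    rng = np.random.default_rng(seed)
    n_each = int(round(sparsity * n_features))
    # |A ∩ B| = j * |A ∪ B|; with |A| = |B| = n: shared = 2jn / (1 + j)
    n_shared = int(round(2 * jaccard * n_each / (1.0 + jaccard)))
    n_own = n_each - n_shared
    pool = rng.permutation(n_features)
    shared, a_own, b_own = (
        pool[:n_shared],
        pool[n_shared : n_shared + n_own],
        pool[n_shared + n_own : n_shared + 2 * n_own],
    )
    maps = {g: np.zeros(n_features) for g in GROUPS}
    shared_signs = rng.choice([-1.0, 1.0], size=n_shared)
    maps["AD"][shared] = effect_size * shared_signs
    maps["FTD"][shared] = effect_size * shared_signs
    maps["AD"][a_own] = effect_size * rng.choice([-1.0, 1.0], size=n_own)
    maps["FTD"][b_own] = effect_size * rng.choice([-1.0, 1.0], size=n_own)
    return maps


def _slope_array(value, n_features: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_features, float(arr))
    if arr.shape != (n_features,):
        raise ValueError(f"slope array shape {arr.shape} != ({n_features},)")
    return arr


def generate_cohort(
    spec: CohortSpec, dims: Sequence[FeatureSetSpec]
) -> tuple[list[SubjectRecord], FeatureTable]:
    """Sample records and a raw feature table; deterministic given the seed."""
    n_features = total_dimension(dims)
    spec.validate(n_features)
    rng = np.random.default_rng(spec.seed)

    slopes = {
        cov: _slope_array(v, n_features) for cov, v in spec.covariate_effects.items()
    }
    baseline = _slope_array(spec.baseline, n_features)
    columns = default_column_names(dims)

    records: list[SubjectRecord] = []
    rows: list[np.ndarray] = []
    sid_counter = 0
    for group in GROUPS:
        n_subjects = int(spec.n_per_group.get(group, 0))
        shift = np.asarray(
            spec.group_effect_maps.get(group, np.zeros(n_features)), dtype=float
        )
        for _ in range(n_subjects):
            sid = f"S{sid_counter:05d}"
            sid_counter += 1
            age0 = float(np.clip(rng.normal(70.0, 8.0), 45.0, 95.0))
            icv = float(rng.normal(1.5e6, 1.5e5))
            sex = Sex.F if rng.random() < 0.5 else Sex.M
            fs = FieldStrength.T3 if rng.random() < 0.5 else FieldStrength.T15
            site = f"site{int(rng.integers(0, 2))}"
            scanner = f"scanner{int(rng.integers(0, 2))}"
            subject_effect = rng.normal(0.0, spec.subject_sd) if spec.subject_sd else 0.0
            for visit in range(spec.scans_per_subject):
                age = age0 + 0.5 * visit
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        visit_id=f"v{visit}",
                        diagnosis=Diagnosis(group),
                        age=age,
                        sex=sex,
                        icv=icv,
                        field_strength=fs,
                        site=site,
                        scanner=scanner,
                    )
                )
                covariate_part = (
                    slopes.get("age", 0.0) * age
                    + slopes.get("sex", 0.0) * (1.0 if sex is Sex.F else 0.0)
                    + slopes.get("icv", 0.0) * icv
                    + slopes.get("field_strength", 0.0)
                    * (1.0 if fs is FieldStrength.T3 else 0.0)
                )
                noise = rng.normal(0.0, 1.0, size=n_features)
                rows.append(
                    baseline
                    + covariate_part
                    + (shift + subject_effect + noise) * spec.noise_sd
                )
    ids = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "visit_id": [r.visit_id for r in records],
        }
    )
    table = FeatureTable(ids, np.array(rows), columns, dims, kind="raw")
    return records, table


def ground_truth(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Per-group indices of features carrying group signal."""
    return {
        g: np.flatnonzero(np.asarray(m))
        for g, m in spec.group_effect_maps.items()
    }
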