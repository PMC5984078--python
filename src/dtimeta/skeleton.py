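"""ROI-level summaries of voxelwise white-matter skeleton values.

Operates on flat, labelled value vectors: an :class:`AtlasLabels` assigns each
skeleton voxel to one atomic tract label (optionally hemisphere-specific, e.g.
``ACR.L``/``ACR.R``) or to the ``PERIPHERY`` sentinel for skeleton voxels
outside the JHU-labelled core.  No geometry or image I/O is involved — means
over label groups are all the downstream statistics need.

Bilateral ROIs are combined by voxel-count weighting, i.e. the combined mean
equals the plain mean over the union of left and right voxels.  Compound ROIs
(CC, CR, IC) are voxel-count-weighted unions of their segments.  The
core/periphery decomposition satisfies the exact reconstruction identity

    n_total * average = n_core * core + n_periphery * periphery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry
from .registry import ATOMIC_ROIS, AVERAGE_FA, COMPOUND_ROIS, PERIPHERY, ROI_REGISTRY


@dataclass(frozen=True)
class AtlasLabels:
    """Flat voxel->label map over a skeleton.

    ``labels`` holds one atomic label per voxel: ``"<ROI>"`` for midline ROIs,
    ``"<ROI>.L"`` / ``"<ROI>.R"`` for paired ROIs, or ``PERIPHERY``.
    """

    labels: np.ndarray  # dtype=object / str, shape (n_voxels,)
    roi_registry: tuple[str, ...] = ROI_REGISTRY

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        if len(self.roi_registry) != 25:
            raise ValueError("registry must enumerate exactly 25 measures")

    @property
    def n_voxels(self) -> int:
        return self.labels.size

    def atomic_of(self, label: str) -> str:
        return label.split(".")[0]

    @property
    def voxel_counts(self) -> dict[str, int]:
        """Voxel count per registry measure (compounds = sum of parts)."""
        atomic = {roi: 0 for roi in ATOMIC_ROIS}
        n_periph = 0
        for lab in self.labels:
            base = self.atomic_of(lab)
            if base == PERIPHERY:
                n_periph += 1
            else:
                atomic[base] += 1
        counts = dict(atomic)
        for comp, parts in COMPOUND_ROIS.items():
            counts[comp] = sum(atomic[p] for p in parts)
        counts[AVERAGE_FA] = self.n_voxels
        counts[PERIPHERY] = n_periph
        return counts


@dataclass(frozen=True)
class SkeletonVolume:
    """Voxelwise values for one subject on the skeleton (one metric)."""

    values: np.ndarray
    metric: str = "FA"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )


@dataclass
class ROISummary:
    """Average / core / periphery decomposition of one skeleton volume."""

    average: float
    core: float
    periphery: float  # NaN when the periphery is empty
    n_total: int
    n_core: int
    n_periphery: int
    roi_means: dict[str, float] = field(default_factory=dict)


def _check_lengths(volume: SkeletonVolume, atlas: AtlasLabels) -> None:
    if volume.values.size != atlas.n_voxels:
        raise ValueError(
            f"volume has {volume.values.size} voxels, atlas has {atlas.n_voxels}"
        )


def roi_means(volume: SkeletonVolume, atlas: AtlasLabels) -> pd.Series:
    """Mean value per registry measure, hemispheres combined by voxel count.

    Returns a Series indexed by the 25-measure registry.  A measure with zero
    voxels in the atlas is reported as NaN (missing), never as zero.
    ``AverageFA`` is the mean over *all* voxels, periphery included.
    """
    _check_lengths(volume, atlas)
    sums = {roi: 0.0 for roi in ATOMIC_ROIS}
    counts = {roi: 0 for roi in ATOMIC_ROIS}
    for lab, v in zip(atlas.labels, volume.values):
        base = atlas.atomic_of(lab)
        if base != PERIPHERY:
            sums[base] += v
            counts[base] += 1
    out: dict[str, float] = {}
    for roi in ATOMIC_ROIS:
        out[roi] = sums[roi] / counts[roi] if counts[roi] else np.nan
    for comp, parts in COMPOUND_ROIS.items():
        n = sum(counts[p] for p in parts)
        out[comp] = sum(sums[p] for p in parts) / n if n else np.nan
    out[AVERAGE_FA] = float(volume.values.mean()) if volume.values.size else np.nan
    return pd.Series(out, name=volume.metric).reindex(list(atlas.roi_registry))


def decompose_core_periphery(
    volume: SkeletonVolume, atlas: AtlasLabels
) -> ROISummary:
    """Split the whole-skeleton mean into JHU-core and periphery components."""
    _check_lengths(volume, atlas)
    bases = np.array([atlas.atomic_of(lab) for lab in atlas.labels], dtype=object)
    is_periph = bases == PERIPHERY
    n_total = atlas.n_voxels
    n_periph = int(is_periph.sum())
    n_core = n_total - n_periph
    if n_core == 0:
        raise ValueError("atlas has no core (JHU-labelled) voxels")
    average = float(volume.values.mean())
    core = float(volume.values[~is_periph].mean())
    if n_periph == 0:
        warnings.warn(
            "atlas has no periphery voxels; periphery mean reported missing",
            stacklevel=2,
        )
        periphery = float("nan")
    else:
        periphery = float(volume.values[is_periph].mean())
    return ROISummary(
        average=average,
        core=core,
        periphery=periphery,
        n_total=n_total,
        n_core=n_core,
        n_periphery=n_periph,
        roi_means=roi_means(volume, atlas).to_dict(),
    )


def make_default_atlas(n_voxels: int = 2000, rng=None) -> AtlasLabels:
    """Synthetic skeleton atlas with template-proportional ROI sizes.

    The real skeleton template (112 889 voxels) is not shipped; this builds a
    scaled-down stand-in whose atomic-ROI voxel counts are proportional to the
    template counts (minimum 2 voxels per ROI, paired ROIs split evenly into
    hemispheres) with the remainder labelled periphery.  Label order is
    deterministic; pass ``rng`` to shuffle voxel order (means are unaffected).
    """
    if n_voxels <= 0:
        raise ValueError("n_voxels must be positive")
    scale = n_voxels / registry.N_SKELETON_VOXELS
    labels: list[str] = []
    for roi, (n_template, midline) in ATOMIC_ROIS.items():
        n_roi = max(2, int(round(n_template * scale)))
        if midline:
            labels.extend([roi] * n_roi)
        else:
            n_left = n_roi // 2
            labels.extend([f"{roi}.L"] * n_left + [f"{roi}.R"] * (n_roi - n_left))
    if len(labels) > n_voxels:
        raise ValueError(
            f"n_voxels={n_voxels} too small for {len(labels)} core voxels"
        )
    labels.extend([PERIPHERY] * (n_voxels - len(labels)))
    arr = np.array(labels, dtype=object)
    if rng is not None:
        rng.shuffle(arr)
    return AtlasLabels(labels=arr)


def atlas_to_frame(atlas: AtlasLabels) -> pd.DataFrame:
    return pd.DataFrame(
        {"voxel_id": np.arange(atlas.n_voxels), "label": atlas.labels}
    )


def atlas_from_frame(df: pd.DataFrame) -> AtlasLabels:
    df = df.sort_values("voxel_id")
    return AtlasLabels(labels=df["label"].to_numpy(dtype=object))


def volume_to_frame(volume: SkeletonVolume) -> pd.DataFrame:
    return pd.DataFrame(
        {"voxel_id": np.arange(volume.values.size), "value": volume.values}
    )


def volume_from_frame(df: pd.DataFrame, metric: str = "FA") -> SkeletonVolume:
    df = df.sort_values("voxel_id")
    return SkeletonVolume(values=df["value"].to_numpy(dtype=float), metric=metric)
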