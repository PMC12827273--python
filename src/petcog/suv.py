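"""Region-wise SUV feature extraction from dynamic PET volumes.

SUV = tissue activity concentration / (injected dose / body weight), with
units reconciled under the unit-density convention (1 g of tissue occupies
1 mL), so for activity in kBq/mL, dose in MBq and weight in kg the kilo
factors cancel:

    suv = activity_kbq_per_ml * body_weight_kg / injected_dose_mbq

Region features are the arithmetic mean of (SUV-converted) voxels inside
each atlas label, computed per frame and then averaged unweighted across
frames, yielding one value per region per subject.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, EmptyRegionError
from .synth import SyntheticPETFixture

log = logging.getLogger(__name__)


def compute_suv(activity, injected_dose: float, body_weight: float):
    """Convert activity concentration (kBq/mL) to unitless SUV.

    ``injected_dose`` in MBq, ``body_weight`` in kg.  Works elementwise on
    arrays.  370 MBq into 74 kg gives 5 kBq/g, so 5 kBq/mL -> SUV 1.0.
    """
    if injected_dose <= 0:
        raise DomainError("injected_dose must be > 0 MBq")
    if body_weight <= 0:
        raise DomainError("body_weight must be > 0 kg")
    activity = np.asarray(activity, dtype=float)
    if np.any(activity[np.isfinite(activity)] < 0):
        raise DomainError("activity must be >= 0")
    out = activity * (body_weight / injected_dose)
    return float(out) if out.ndim == 0 else out


def extract_region_means(
    volume: np.ndarray,
    atlas: np.ndarray,
    labels: "list[int] | None" = None,
) -> dict[int, float]:
    """Mean of ``volume`` over the voxels of each atlas label (>= 1).

    Background (label 0) is excluded.  ``labels=None`` means every label
    present in the atlas; explicitly requested labels with no voxels raise
    :class:`EmptyRegionError`.  NaN voxels are excluded from the mean with a
    logged count.
    """
    volume = np.asarray(volume, dtype=float)
    atlas = np.asarray(atlas)
    if volume.shape != atlas.shape:
        raise AlignmentError(
            f"volume shape {volume.shape} does not match atlas shape {atlas.shape}"
        )
    if np.any(atlas < 0):
        raise DomainError("atlas labels must be non-negative integers")
    present = np.unique(atlas)
    present = present[present >= 1]
    if labels is None:
        wanted = [int(l) for l in present]
    else:
        wanted = [int(l) for l in labels]
        missing = sorted(set(wanted) - set(int(l) for l in present))
        if missing:
            raise EmptyRegionError(missing[0])

    flat_labels = atlas.ravel()
    flat_vals = volume.ravel()
    nan_mask = np.isnan(flat_vals)
    n_nan = int(np.count_nonzero(nan_mask & (flat_labels > 0)))
    if n_nan:
        log.warning("excluding %d NaN voxels from region means", n_nan)
    valid = ~nan_mask
    sums = np.bincount(flat_labels[valid], weights=flat_vals[valid])
    counts = np.bincount(flat_labels[valid])
    out = {}
    for label in wanted:
        if label >= len(counts) or counts[label] == 0:
            raise EmptyRegionError(label)
        out[label] = float(sums[label] / counts[label])
    return out


def average_frames(per_frame_means: np.ndarray) -> np.ndarray:
    """Unweighted mean across frames of a (region x frame) matrix."""
    m = np.asarray(per_frame_means, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    if m.shape[1] < 1:
        raise DomainError("at least one frame is required")
    if np.isnan(m).any():
        raise DomainError("per-frame means contain missing cells")
    return m.mean(axis=1)


def extract_subject_features(
    volume: np.ndarray,
    atlas: np.ndarray,
    injected_dose: float,
    body_weight: float,
    labels: "list[int] | None" = None,
) -> dict[int, float]:
    """SUV-convert a 4-D volume, take region means per frame, average frames."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim == 3:
        volume = volume[..., None]
    if volume.ndim != 4:
        raise AlignmentError("volume must be 3-D or 4-D (x, y, z[, frame])")
    if volume.shape[:3] != np.asarray(atlas).shape:
        raise AlignmentError(
            f"volume spatial shape {volume.shape[:3]} does not match atlas "
            f"shape {np.asarray(atlas).shape}"
        )
    suv = compute_suv(volume, injected_dose, body_weight)
    if labels is None:
        present = np.unique(np.asarray(atlas))
        labels = [int(l) for l in present[present >= 1]]
    per_frame = np.empty((len(labels), suv.shape[3]))
    for t in range(suv.shape[3]):
        means = extract_region_means(suv[..., t], atlas, labels=labels)
        per_frame[:, t] = [means[l] for l in labels]
    averaged = average_frames(per_frame)
    return {l: float(v) for l, v in zip(labels, averaged)}


def build_feature_table(
    subjects,
    region_labels: "dict[int, str] | None" = None,
) -> pd.DataFrame:
    """Build the subject x region mean-SUV table.

    ``subjects`` is an iterable of either ``(subject_id, SyntheticPETFixture)``
    pairs or ``(subject_id, volume, atlas, injected_dose, body_weight)``
    tuples.  Column order follows ascending atlas label order; an optional
    ``region_labels`` mapping renames integer labels to region names.
    """
    rows = []
    expected: list[int] | None = None
    for entry in subjects:
        if len(entry) == 2 and isinstance(entry[1], SyntheticPETFixture):
            sid, fx = entry
            vol, atlas, dose, weight = fx.volume, fx.atlas, fx.injected_dose, fx.body_weight
            labels = sorted(fx.true_region_means)
        else:
            sid, vol, atlas, dose, weight = entry
            labels = None
        try:
            feats = extract_subject_features(vol, atlas, dose, weight, labels=labels)
        except Exception as exc:
            exc.args = (f"subject {sid}: " + (str(exc.args[0]) if exc.args else ""),)
            raise
        if expected is None:
            expected = sorted(feats)
        elif sorted(feats) != expected:
            raise AlignmentError(f"subject {sid}: region labels differ from first subject")
        rows.append({"subject_id": sid, **{l: feats[l] for l in expected}})
    table = pd.DataFrame(rows)
    if region_labels:
        table = table.rename(columns=region_labels)
    return table


def save_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
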