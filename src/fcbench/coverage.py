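"""Voxel-coverage masking and parcel rejection on labelled 3-D/4-D arrays.

The procedure has three steps, applied to per-subject temporal-mean signal
images on a common grid:

1. per-subject mask: voxels whose mean signal is at least ``fraction``
   (default 0.6) of the subject's global reference signal;
2. consensus mask: voxels present in at least ``threshold`` (default 50%,
   inclusive) of the subject masks;
3. parcel filter: parcels with less than ``min_fraction`` (default 10%,
   strict) of their voxels inside the consensus mask are rejected.

The global reference for step 1 is the mean signal over nonzero voxels,
which is robust to zero padding around the imaged volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def subject_mask(mean_signal: np.ndarray, fraction: float = 0.6) -> np.ndarray:
    """Binary mask of voxels with signal >= fraction x global reference.

    The global reference is the mean of ``mean_signal`` over its nonzero
    voxels.  With ``fraction`` slightly above 1 only strictly-above-reference
    voxels survive (boundary behaviour follows directly from the >= rule).
    """
    sig = np.asarray(mean_signal, dtype=float)
    if not 0 < fraction:
        raise ValueError("fraction must be positive")
    nonzero = sig != 0
    if not nonzero.any():
        raise ValueError("all-zero signal image: no global reference")
    reference = sig[nonzero].mean()
    return sig >= fraction * reference


def consensus_mask(masks: list[np.ndarray], threshold: float = 0.5) -> np.ndarray:
    """Voxels present in at least ceil(threshold * n_subjects) subject masks.

    The boundary is inclusive: with 4 subjects and threshold 0.5, presence
    in exactly 2 masks keeps the voxel.
    """
    if not masks:
        raise ValueError("need at least one mask")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    counts = np.sum([np.asarray(m, dtype=bool) for m in masks], axis=0)
    need = int(np.ceil(threshold * len(masks)))
    return counts >= need


@dataclass
class CoverageResult:
    """Outcome of the coverage-filtering procedure."""

    subject_masks: list[np.ndarray]
    consensus: np.ndarray
    parcel_coverage: dict[int, float]
    kept_parcels: list[int]


def parcel_coverage_filter(consensus: np.ndarray, labels: np.ndarray,
                           min_fraction: float = 0.10) -> tuple[dict[int, float], list[int]]:
    """Per-parcel coverage fractions and the kept-parcel list.

    coverage_p = |voxels of parcel p inside the consensus mask| / |voxels of p|.
    Parcels with coverage strictly below ``min_fraction`` are rejected
    (coverage exactly at the threshold is kept).  Label 0 is background.
    Empty parcel ids within 1..labels.max() raise, listing the offenders.
    """
    labels = np.asarray(labels)
    if labels.shape != np.asarray(consensus).shape:
        raise ValueError("labels and consensus shapes differ")
    if (labels < 0).any():
        raise ValueError("labels must be nonnegative integers")
    consensus = np.asarray(consensus, dtype=bool)
    max_label = int(labels.max())
    sizes = np.bincount(labels.ravel(), minlength=max_label + 1)
    covered = np.bincount(labels.ravel(), weights=consensus.ravel().astype(float),
                          minlength=max_label + 1)
    empty = [p for p in range(1, max_label + 1) if sizes[p] == 0]
    if empty:
        raise ValueError(f"parcel ids with no voxels: {empty}")
    coverage = {p: float(covered[p] / sizes[p]) for p in range(1, max_label + 1)}
    kept = sorted(p for p, c in coverage.items() if c >= min_fraction)
    return coverage, kept


def coverage_pipeline(mean_signals: list[np.ndarray], labels: np.ndarray,
                      fraction: float = 0.6, threshold: float = 0.5,
                      min_fraction: float = 0.10) -> CoverageResult:
    """Run the full subject-mask -> consensus -> parcel-filter chain."""
    masks = [subject_mask(s, fraction=fraction) for s in mean_signals]
    cons = consensus_mask(masks, threshold=threshold)
    cov, kept = parcel_coverage_filter(cons, labels, min_fraction=min_fraction)
    return CoverageResult(masks, cons, cov, kept)
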