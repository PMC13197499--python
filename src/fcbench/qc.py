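"""Motion summaries, QC-FC, strategy-similarity matrices and ICC reliability.

Motion conventions
------------------
Framewise displacement follows the Power convention: absolute backward
differences of the six rigid-body parameters, rotations converted to arc
length on a 50 mm sphere.  Relative RMS displacement follows the Jenkinson
convention: the RMS deviation of the frame-to-frame rigid transform over an
80 mm sphere.  Both radii are exposed as keyword arguments.

ICC variants are computed from the two-way subject x rater mean squares of
the classical ANOVA decomposition; no library shortcut is used, so the
formulas below are the single source of truth for the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


def _motion_array(motion) -> np.ndarray:
    """Coerce a T x 6 motion table (DataFrame or array) to a float array.

    DataFrames are reordered to the canonical fMRIPrep column order;
    plain arrays are assumed to already be (trans_x..z, rot_x..z).
    """
    if isinstance(motion, pd.DataFrame):
        missing = [c for c in MOTION_COLUMNS if c not in motion.columns]
        if missing:
            raise ValueError(f"motion table missing columns: {missing}")
        arr = motion.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    else:
        arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"expected a T x 6 motion array, got shape {arr.shape}")
    return arr


def framewise_displacement(motion, rotation_radius: float = 50.0) -> np.ndarray:
    """Per-volume framewise displacement (mm), Power convention.

    FD_t = sum |Delta trans| + radius * sum |Delta rot|, with FD_0 = 0.
    Rotations must be in radians.
    """
    arr = _motion_array(motion)
    d = np.abs(np.diff(arr, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def _affine(params: np.ndarray) -> np.ndarray:
    """4x4 rigid-body affine from (tx, ty, tz, rx, ry, rz), radians.

    Rotation composed as Rx @ Ry @ Rz (a fixed documented convention; the
    relative-RMS metric is insensitive to the order for small angles).
    """
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rx @ Ry @ Rz
    M[:3, 3] = (tx, ty, tz)
    return M


def relative_rmsd(motion, radius: float = 80.0) -> np.ndarray:
    """Per-volume relative RMS displacement (mm), Jenkinson convention.

    For successive volumes with rigid transforms M_{t-1}, M_t, let
    D = M_t @ inv(M_{t-1}) - I, A = D[:3,:3], b = D[:3,3].  Then

        rms_t = sqrt(radius**2 / 5 * trace(A.T @ A) + b.T @ b)

    and rms_0 = 0.  With zero rotations this reduces to the Euclidean
    step length of the translation parameters.
    """
    arr = _motion_array(motion)
    out = np.zeros(len(arr))
    prev = _affine(arr[0])
    for t in range(1, len(arr)):
        cur = _affine(arr[t])
        D = cur @ np.linalg.inv(prev) - np.eye(4)
        A, b = D[:3, :3], D[:3, 3]
        out[t] = np.sqrt(radius**2 / 5.0 * np.trace(A.T @ A) + b @ b)
        prev = cur
    return out


def mean_relative_rmsd(motion, radius: float = 80.0) -> float:
    """Scan-level motion scalar: mean of relative RMS over volumes 2..T."""
    rms = relative_rmsd(motion, radius=radius)
    return float(rms[1:].mean()) if len(rms) > 1 else 0.0


@dataclass
class MotionSummary:
    """Per-scan motion quality summary."""

    framewise_displacement: np.ndarray
    relative_rmsd: np.ndarray
    mean_relative_rmsd: float


def motion_summary(motion) -> MotionSummary:
    fd = framewise_displacement(motion)
    rms = relative_rmsd(motion)
    return MotionSummary(fd, rms, float(rms[1:].mean()) if len(rms) > 1 else 0.0)


# ---------------------------------------------------------------------------
# QC-FC
# ---------------------------------------------------------------------------

def qcfc(edges: np.ndarray, motion: np.ndarray) -> tuple[np.ndarray, float]:
    """QC-FC: per-edge |Pearson r| between edge weights and subject motion.

    Parameters
    ----------
    edges : (n_subjects, n_edges) array of FC edge values.
    motion : (n_subjects,) scalar motion summaries (mean relative RMSD).

    Returns
    -------
    per_edge : (n_edges,) array of absolute correlations; edges with zero
        across-subject variance are NaN (excluded from the summary).
    score : mean of the defined per-edge values.  Lower means less
        residual motion contamination in the connectivity estimates.
    """
    edges = np.asarray(edges, dtype=float)
    motion = np.asarray(motion, dtype=float)
    if edges.ndim != 2:
        raise ValueError("edges must be (subjects, edges)")
    if edges.shape[0] != motion.shape[0]:
        raise ValueError("edges and motion disagree on subject count")
    if edges.shape[0] < 4:
        raise ValueError("QC-FC needs at least 4 subjects")
    m = motion - motion.mean()
    denom_m = np.sqrt((m**2).sum())
    if denom_m == 0:
        raise ValueError("motion summary has zero variance across subjects")
    e = edges - edges.mean(axis=0)
    denom_e = np.sqrt((e**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (e.T @ m) / (denom_e * denom_m)
    per_edge = np.abs(r)
    per_edge[denom_e == 0] = np.nan
    valid = ~np.isnan(per_edge)
    if not valid.any():
        raise ValueError("all edges have zero variance")
    return per_edge, float(per_edge[valid].mean())


# ---------------------------------------------------------------------------
# Similarity between denoising strategies
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Mean within-subject correlation between flattened FC matrices.

    ``labels`` pairs (strategy id, state) with the rows/columns of
    ``values``; for the full benchmark this is a 32 x 32 matrix
    (16 strategies x 2 states).
    """

    values: np.ndarray
    labels: list[tuple[int, str]]

    def frame(self) -> pd.DataFrame:
        idx = [f"s{s:02d}_{st}" for s, st in self.labels]
        return pd.DataFrame(self.values, index=idx, columns=idx)


def strategy_similarity(
    vectors: Mapping[str, Mapping[tuple[int, str], np.ndarray]],
    strategies: Sequence[int] | None = None,
    states: Sequence[str] = ("EO", "EC"),
) -> SimilarityMatrix:
    """Per-subject correlation of FC vectors across (strategy, state), averaged.

    ``vectors[subject][(strategy_id, state)]`` is one flattened FC matrix.
    Every subject must supply every condition; missing conditions raise with
    the full (subject, strategy, state) list.
    """
    if not vectors:
        raise ValueError("no subjects supplied")
    if strategies is None:
        strategies = sorted({s for conds in vectors.values() for (s, _) in conds})
    labels = [(s, st) for s in strategies for st in states]
    missing = [
        (subj, s, st)
        for subj, conds in vectors.items()
        for (s, st) in labels
        if (s, st) not in conds
    ]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    acc = None
    for subj, conds in vectors.items():
        mat = np.vstack([np.asarray(conds[lab], dtype=float) for lab in labels])
        corr = np.corrcoef(mat)
        acc = corr if acc is None else acc + corr
    return SimilarityMatrix(acc / len(vectors), labels)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclass
class ICCComponents:
    """Mean squares of the two-way subject x rater ANOVA layout."""

    BMS: float  # between-subject mean square
    WMS: float  # within-subject mean square
    RMS: float  # between-rater mean square
    EMS: float  # residual (error) mean square
    n: int
    k: int


@dataclass
class ICCResult:
    icc31: float
    icc21: float
    icc11: float
    components: ICCComponents


def icc(data: np.ndarray) -> ICCResult:
    """ICC(3,1), ICC(2,1) and ICC(1,1) for an n x k subjects-by-raters table.

    ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS)            two-way mixed, consistency
    ICC(2,1) = (BMS - EMS) / (BMS + (k-1) EMS + k (RMS - EMS) / n)
                                                           two-way random, agreement
    ICC(1,1) = (BMS - WMS) / (BMS + (k-1) WMS)            one-way random, agreement

    No silent clipping: degenerate inputs (zero total variance) raise.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be 2-D (subjects x raters)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need n >= 3 subjects and k >= 2 raters, got {n} x {k}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in data")
    grand = x.mean()
    sst = ((x - grand) ** 2).sum()
    if sst <= 0:
        raise ValueError("zero total variance: ICC undefined")
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    ssb = k * ((rows - grand) ** 2).sum()          # between subjects
    ssc = n * ((cols - grand) ** 2).sum()          # between raters
    ssw = ((x - rows[:, None]) ** 2).sum()         # within subjects
    sse = sst - ssb - ssc                          # residual
    comp = ICCComponents(
        BMS=ssb / (n - 1),
        WMS=ssw / (n * (k - 1)),
        RMS=ssc / (k - 1),
        EMS=sse / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )
    icc31 = (comp.BMS - comp.EMS) / (comp.BMS + (k - 1) * comp.EMS)
    icc21 = (comp.BMS - comp.EMS) / (
        comp.BMS + (k - 1) * comp.EMS + k * (comp.RMS - comp.EMS) / n
    )
    icc11 = (comp.BMS - comp.WMS) / (comp.BMS + (k - 1) * comp.WMS)
    return ICCResult(float(icc31), float(icc21), float(icc11), comp)


def mask_edges(group_mean: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Boolean mask keeping the strongest edges of a group-mean FC vector.

    Keeps the ceil((1 - percentile/100) * E) edges with the largest
    |group-mean| value.  Ties are broken by index order (stable sort), so
    an all-equal input keeps the first block of edges - documented
    degenerate behaviour.  Absolute values are used because tangent and
    partial-correlation edges are signed.
    """
    v = np.abs(np.asarray(group_mean, dtype=float))
    if v.ndim != 1 or v.size == 0:
        raise ValueError("group_mean must be a non-empty 1-D edge vector")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    # ceil((1 - p/100) * E) without float-precision spill at exact multiples
    n_keep = v.size - int(np.floor(percentile * v.size / 100.0 + 1e-9))
    order = np.argsort(-v, kind="stable")
    mask = np.zeros(v.size, dtype=bool)
    mask[order[:n_keep]] = True
    return mask
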