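"""Confound design matrices for the 16 denoising strategies and residualization.

The strategy table mirrors the standard benchmark layout: eight base recipes
combining head-motion-parameter (HMP) expansions, CompCor variants and
ICA-AROMA, and the same eight with four global-signal regressors (GSR)
appended.  Every strategy additionally receives an intercept and the
discrete-cosine drift basis.

Conventions (documented package choices):

* temporal derivative = backward difference with a leading zero (the
  fMRIPrep convention);
* the fourth GSR column is literally the derivative of the squared global
  signal (diff of squares), not the square of the derivative;
* the cosine high-pass cutoff defaults to 128 s;
* rank-deficient design columns are dropped in QR pivot order and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.linalg

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import ConfoundTable

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class StrategySpec:
    """One denoising recipe.

    ``hmp`` is None for AROMA strategies (motion variance is handled by the
    AROMA components themselves); otherwise "HMP12" or "HMP24".
    """

    id: int
    hmp: str | None
    compcor: str  # none | a_fixed10 | a_var50 | t_plus_a_var50
    aroma: str    # none | nonaggressive | aggressive
    gsr: bool
    name: str


def _base_strategies() -> list[StrategySpec]:
    return [
        StrategySpec(1, "HMP24", "none", "none", False, "24HMP"),
        StrategySpec(2, "HMP12", "a_fixed10", "none", False, "aCompCor+12HMP"),
        StrategySpec(3, "HMP12", "a_var50", "none", False, "aCompCor(50%)+12HMP"),
        StrategySpec(4, "HMP24", "a_fixed10", "none", False, "aCompCor+24HMP"),
        StrategySpec(5, "HMP24", "a_var50", "none", False, "aCompCor(50%)+24HMP"),
        StrategySpec(6, "HMP24", "t_plus_a_var50", "none", False,
                     "tCompCor+aCompCor(50%)+24HMP"),
        StrategySpec(7, None, "a_fixed10", "nonaggressive", False,
                     "AROMA-NonAggressive+aCompCor"),
        StrategySpec(8, None, "a_fixed10", "aggressive", False,
                     "AROMA-Aggressive+aCompCor"),
    ]


def all_strategies() -> tuple[StrategySpec, ...]:
    """The 16 denoising strategies; ids 9-16 are ids 1-8 with GSR added."""
    base = _base_strategies()
    with_gsr = [
        replace(s, id=s.id + 8, gsr=True, name=s.name + "+GSR") for s in base
    ]
    return tuple(base + with_gsr)


def get_strategy(strategy_id: int) -> StrategySpec:
    for s in all_strategies():
        if s.id == strategy_id:
            return s
    raise KeyError(f"no strategy with id {strategy_id} (valid: 1..16)")


# ---------------------------------------------------------------------------
# Regressor blocks
# ---------------------------------------------------------------------------

def _derivative(x: np.ndarray) -> np.ndarray:
    """Backward difference with a leading zero row."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def expand_motion(motion, variant: str) -> pd.DataFrame:
    """Expand 6 rigid-body parameters to the 12- or 24-regressor HMP block.

    HMP12 = parameters + temporal derivatives; HMP24 additionally squares
    both blocks.
    """
    if isinstance(motion, pd.DataFrame):
        missing = [c for c in MOTION_COLUMNS if c not in motion.columns]
        if missing:
            raise ValueError(f"motion table missing columns: {missing}")
        arr = motion.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    else:
        arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"expected T x 6 motion input, got {arr.shape}")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 volumes")
    names = list(MOTION_COLUMNS)
    deriv = _derivative(arr)
    blocks = [arr, deriv]
    cols = names + [f"{c}_derivative1" for c in names]
    if variant == "HMP24":
        blocks += [arr**2, deriv**2]
        cols += [f"{c}_power2" for c in names]
        cols += [f"{c}_derivative1_power2" for c in names]
    elif variant != "HMP12":
        raise ValueError(f"unknown HMP variant {variant!r}")
    return pd.DataFrame(np.hstack(blocks), columns=cols)


def gsr_block(global_signal) -> pd.DataFrame:
    """The four global-signal regressors.

    Order: the global signal, its derivative, its square, and the derivative
    of its square (diff of the squared series).
    """
    g = np.asarray(global_signal, dtype=float).ravel()
    if g.size < 3:
        raise ValueError("need at least 3 volumes")
    g2 = g**2
    data = np.column_stack([g, _derivative(g[:, None]).ravel(), g2,
                            _derivative(g2[:, None]).ravel()])
    return pd.DataFrame(
        data,
        columns=["global_signal", "global_signal_derivative1",
                 "global_signal_power2", "global_signal_power2_derivative1"],
    )


def cosine_basis(T: int, tr: float, cutoff: float = 128.0) -> pd.DataFrame:
    """Discrete-cosine drift basis for periods longer than ``cutoff`` seconds.

    m = floor(2 * T * tr / cutoff) columns (DC excluded; the intercept is a
    separate design column).  Columns are orthogonal and unit-normalized.
    Returns zero columns with a warning when the scan is shorter than the
    cutoff period.
    """
    if T < 2 or tr <= 0:
        raise ValueError("need T >= 2 volumes and tr > 0")
    if T * tr <= cutoff:
        warnings.warn(
            f"scan duration {T * tr:.1f}s <= cutoff {cutoff}s: no drift columns",
            stacklevel=2,
        )
        return pd.DataFrame(index=range(T))
    m = int(np.floor(2 * T * tr / cutoff))
    m = min(m, T - 1)
    t = np.arange(T)
    cols = {}
    for k in range(1, m + 1):
        c = np.cos(np.pi * k * (2 * t + 1) / (2 * T))
        cols[f"cosine_{k - 1:02d}"] = c * np.sqrt(2.0 / T)
    return pd.DataFrame(cols)


def select_acompcor(components: pd.DataFrame, shares: np.ndarray,
                    mode: str) -> pd.DataFrame:
    """Select anatomical-CompCor columns by count or explained variance.

    ``a_fixed10`` keeps the first min(10, K) columns (warning when K < 10);
    ``a_var50`` keeps the smallest prefix whose cumulative explained-variance
    share reaches 0.50.  Shares must be positive and sorted non-increasing.
    """
    shares = np.asarray(shares, dtype=float)
    if shares.size != components.shape[1]:
        raise ValueError("one share per component required")
    if (shares <= 0).any() or (np.diff(shares) > 1e-12).any():
        raise ValueError("shares must be positive and sorted non-increasing")
    if mode == "a_fixed10":
        if components.shape[1] < 10:
            warnings.warn(
                f"only {components.shape[1]} aCompCor columns available "
                "(10 requested)", stacklevel=2)
        return components.iloc[:, : min(10, components.shape[1])]
    if mode == "a_var50":
        cum = np.cumsum(shares)
        # smallest prefix reaching 50% cumulative share; all columns if the
        # table never gets there
        k = int(np.searchsorted(cum, 0.50 - 1e-12) + 1)
        k = min(k, components.shape[1])
        return components.iloc[:, :k]
    raise ValueError(f"unknown aCompCor mode {mode!r}")


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """A T x p confound design with per-column provenance.

    ``provenance`` maps each column name to the rule that emitted it
    (intercept, cosine, hmp, acompcor, tcompcor, aroma, gsr).  ``dropped``
    lists columns removed by rank-deficiency pruning.
    """

    frame: pd.DataFrame
    provenance: dict[str, str]
    dropped: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def n_nuisance(self) -> int:
        """Regressor count excluding the intercept and cosine drift columns."""
        return sum(1 for v in self.provenance.values()
                   if v not in ("intercept", "cosine"))


def _prune_rank_deficient(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    X = frame.to_numpy(dtype=float)
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    _, R, piv = scipy.linalg.qr(X / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps * 1e3 if diag.size else 0.0
    keep_rank = int((diag > tol).sum())
    keep = sorted(piv[:keep_rank])
    dropped = [frame.columns[i] for i in sorted(piv[keep_rank:])]
    return frame.iloc[:, keep], dropped


def assemble_design(spec: StrategySpec, confounds: "ConfoundTable",
                    keep_aroma_in_design: bool | None = None) -> DesignMatrix:
    """Build the confound design matrix for one strategy.

    Intercept and cosine columns are always present.  For AROMA strategies the
    HMP block is omitted; aggressive AROMA places the noise-flagged component
    columns directly in the design, while non-aggressive AROMA leaves them out
    (that removal happens in :func:`aroma_regress` before residualization).
    """
    df = confounds.data
    T = len(df)
    blocks: list[pd.DataFrame] = []
    prov: dict[str, str] = {}

    def add(block: pd.DataFrame, rule: str) -> None:
        blocks.append(block)
        prov.update({c: rule for c in block.columns})

    add(pd.DataFrame({"intercept": np.ones(T)}), "intercept")
    cosine_cols = [c for c in df.columns if c.startswith("cosine_")]
    if cosine_cols:
        add(df[cosine_cols], "cosine")

    if spec.aroma == "none":
        missing = [c for c in MOTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"confounds missing motion columns: {missing}")
        add(expand_motion(df, spec.hmp), "hmp")
    else:
        aroma_cols = [c for c in df.columns if c.startswith("aroma_motion_")]
        if not aroma_cols:
            raise ValueError("confounds missing aroma_motion_* columns")
        if keep_aroma_in_design is None:
            keep_aroma_in_design = spec.aroma == "aggressive"
        if keep_aroma_in_design:
            flags = np.asarray(confounds.aroma_noise_flags, dtype=bool)
            noise = [c for c, f in zip(aroma_cols, flags) if f]
            add(df[noise], "aroma")

    if spec.compcor != "none":
        a_cols = [c for c in df.columns if c.startswith("a_comp_cor_")]
        if not a_cols:
            raise ValueError("confounds missing a_comp_cor_* columns")
        acomp = df[a_cols]
        if spec.compcor in ("a_fixed10", "a_var50"):
            add(select_acompcor(acomp, confounds.acompcor_shares, spec.compcor),
                "acompcor")
        elif spec.compcor == "t_plus_a_var50":
            t_cols = [c for c in df.columns if c.startswith("t_comp_cor_")]
            if not t_cols:
                raise ValueError("confounds missing t_comp_cor_* columns")
            add(df[t_cols], "tcompcor")
            add(select_acompcor(acomp, confounds.acompcor_shares, "a_var50"),
                "acompcor")
        else:
            raise ValueError(f"unknown compcor mode {spec.compcor!r}")

    if spec.gsr:
        if "global_signal" not in df.columns:
            raise ValueError("confounds missing global_signal column")
        add(gsr_block(df["global_signal"]), "gsr")

    frame = pd.concat(blocks, axis=1)
    frame, dropped = _prune_rank_deficient(frame)
    if frame.shape[1] >= T:
        raise ValueError(
            f"design has p={frame.shape[1]} >= T={T} columns; cannot residualize")
    prov = {c: prov[c] for c in frame.columns}
    return DesignMatrix(frame, prov, dropped)


def residualize(Y: np.ndarray, X) -> np.ndarray:
    """OLS residuals of each time-series column against the design.

    The result is orthogonal to every design column to numerical tolerance.
    """
    if isinstance(X, DesignMatrix):
        X = X.matrix
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("Y and X must be 2-D with matching row counts")
    if X.shape[1] >= X.shape[0]:
        raise ValueError("design must have p < T")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient; prune it first")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def aroma_regress(Y: np.ndarray, components: np.ndarray,
                  noise_flags, mode: str) -> np.ndarray:
    """ICA-AROMA style component removal.

    aggressive: residualize Y against the noise-flagged columns alone (their
    full time series is removed).  nonaggressive: fit Y on ALL components
    jointly and subtract only the fitted contribution of the noise columns,
    preserving variance shared with retained components.
    """
    Y = np.asarray(Y, dtype=float)
    C = np.asarray(components, dtype=float)
    flags = np.asarray(noise_flags, dtype=bool)
    if C.shape[1] != flags.size:
        raise ValueError("one noise flag per component required")
    if not flags.any():
        return Y.copy()
    if mode == "aggressive":
        return residualize(Y, C[:, flags])
    if mode != "nonaggressive":
        raise ValueError(f"unknown AROMA mode {mode!r}")
    if flags.all():
        warnings.warn("all components flagged as noise: nonaggressive removal "
                      "behaves as aggressive", stacklevel=2)
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C[:, flags] @ beta[flags]


def clean_scan(spec: StrategySpec, Y: np.ndarray,
               confounds: "ConfoundTable") -> np.ndarray:
    """Apply one full denoising strategy to a T x R ROI time-series matrix."""
    if spec.aroma == "nonaggressive":
        df = confounds.data
        aroma_cols = [c for c in df.columns if c.startswith("aroma_motion_")]
        Y = aroma_regress(Y, df[aroma_cols].to_numpy(float),
                          confounds.aroma_noise_flags, "nonaggressive")
    design = assemble_design(spec, confounds)
    return residualize(Y, design)
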