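"""Matched-pair factor comparisons via subject-level sign-flip tests + BH-FDR.

To compare two levels of one pipeline factor (say GSR on vs off), all
pipeline pairs that differ only in that factor are matched, per-subject mean
Brier-score differences are averaged over the matched pairs, and the mean
difference is tested against a null built by randomly flipping the sign of
each subject's difference.  p-values are corrected with Benjamini-Hochberg
within each factor.

With the full design - 4 FC measures, 4 atlases, 8 strategy families, GSR
on/off, tested in both transfer directions - the comparison count is
(C(4,2) + C(4,2) + C(8,2) + C(2,2)) * 2 = 82.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

#: subject counts at or below which the sign-flip null is enumerated exactly
EXHAUSTIVE_LIMIT = 12


@dataclass
class MatchedPairSet:
    """All pipeline pairs isolating one (factor, level A, level B) contrast."""

    factor: str
    level_a: object
    level_b: object
    pairs: list[tuple[str, str]]  # (cell_id_A, cell_id_B)


@dataclass
class TestResult:
    factor: str
    level_a: object
    level_b: object
    delta: float          # observed mean difference (A - B)
    p_value: float
    n_subjects: int
    method: str           # "exhaustive" or "monte_carlo"
    p_fdr: float | None = None
    significant: bool | None = None


def comparison_count(factor_levels: Mapping[str, int], n_directions: int = 2) -> int:
    """Total pairwise comparisons: sum over factors of C(levels, 2) x directions."""
    return sum(comb(L, 2) for L in factor_levels.values()) * n_directions


def enumerate_pairs(cells: pd.DataFrame, factors: Sequence[str],
                    ) -> list[MatchedPairSet]:
    """Matched pipeline pairs for every factor-level contrast.

    ``cells`` needs a ``cell_id`` column plus one column per factor; two
    cells are matched when they agree on every factor except the one under
    test.  Duplicate cell ids or missing factor columns raise.
    """
    missing = [f for f in factors if f not in cells.columns]
    if missing:
        raise ValueError(f"cells table missing factor columns: {missing}")
    if cells.cell_id.duplicated().any():
        raise ValueError("duplicate cell_id in grid metadata")
    out = []
    for factor in factors:
        others = [f for f in factors if f != factor]
        levels = sorted(cells[factor].unique(), key=str)
        for a, b in combinations(levels, 2):
            sub_a = cells[cells[factor] == a]
            sub_b = cells[cells[factor] == b]
            by_key = {}
            for _, row in sub_b.iterrows():
                by_key.setdefault(tuple(row[f] for f in others),
                                  []).append(row.cell_id)
            pairs = []
            for _, row in sub_a.iterrows():
                for cid in by_key.get(tuple(row[f] for f in others), []):
                    pairs.append((row.cell_id, cid))
            out.append(MatchedPairSet(factor, a, b, pairs))
    return out


def subject_diffs(pairs: Sequence[tuple[pd.Series, pd.Series]]) -> pd.Series:
    """Per-subject mean Brier difference, averaged over matched pipeline pairs.

    Each element of ``pairs`` holds the per-subject mean Brier scores of
    pipelines A and B on the same test subjects.
    """
    if not pairs:
        raise ValueError("no matched pairs supplied")
    diffs = []
    for a, b in pairs:
        if not a.index.equals(b.index):
            b = b.reindex(a.index)
            if b.isna().any():
                raise ValueError("matched pair evaluated on different subjects")
        diffs.append(a - b)
    return pd.concat(diffs, axis=1).mean(axis=1)


def sign_flip_test(diffs, n_perm: int = 5000, seed: int = 0,
                   exhaustive_limit: int = EXHAUSTIVE_LIMIT) -> TestResult:
    """Two-sided sign-flip randomization test of mean(diffs) = 0.

    Null distribution: random independent +/-1 flips per subject.  For
    n <= ``exhaustive_limit`` subjects all 2^n flips are enumerated and the
    p-value is exact; otherwise ``n_perm`` Monte-Carlo draws are used with
    the add-one correction p = (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1).
    An all-zero difference vector has p = 1 by construction.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or d.size < 3:
        raise ValueError("need a 1-D vector of at least 3 subject differences")
    n = d.size
    t_obs = d.mean()
    if np.all(d == 0):
        return TestResult("", None, None, 0.0, 1.0, n, "degenerate")
    if n <= exhaustive_limit:
        # all sign patterns via the bits of 0..2^n-1
        codes = np.arange(2**n, dtype=np.uint64)[:, None]
        bits = (codes >> np.arange(n, dtype=np.uint64)) & 1
        signs = 1.0 - 2.0 * bits
        t_null = signs @ d / n
        p = float((np.abs(t_null) >= np.abs(t_obs) - 1e-12).mean())
        method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
        t_null = signs @ d / n
        p = float((1 + (np.abs(t_null) >= np.abs(t_obs) - 1e-15).sum())
                  / (n_perm + 1))
        method = "monte_carlo"
    return TestResult("", None, None, float(t_obs), p, n, method)


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def run_factor_tests(brier_tables: Mapping[str, pd.Series],
                     cells: pd.DataFrame, factors: Sequence[str],
                     n_perm: int = 5000, seed: int = 0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Full matched-pair analysis over one direction's grid results.

    ``brier_tables`` maps cell_id to per-subject mean Brier scores.  BH-FDR
    is applied within each factor.  Returns one row per factor-level pair.
    """
    sets = enumerate_pairs(cells, factors)
    rows = []
    for i, ps in enumerate(sets):
        if not ps.pairs:
            continue
        diffs = subject_diffs([(brier_tables[a], brier_tables[b])
                               for a, b in ps.pairs])
        res = sign_flip_test(diffs.to_numpy(), n_perm=n_perm, seed=seed + i)
        rows.append({"factor": ps.factor, "level_a": ps.level_a,
                     "level_b": ps.level_b, "n_pairs": len(ps.pairs),
                     "delta": res.delta, "p_value": res.p_value,
                     "method": res.method, "n_subjects": res.n_subjects})
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    table["significant"] = False
    for factor in table.factor.unique():
        m = table.factor == factor
        p_adj, rej = bh_fdr(table.loc[m, "p_value"].to_numpy(), alpha=alpha)
        table.loc[m, "p_fdr"] = p_adj
        table.loc[m, "significant"] = rej
    return table
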