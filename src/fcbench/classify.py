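"""PCA + logistic-regression classification of EO vs EC edge vectors.

Protocols
---------
cross_site : train on every usable scan of the source site, test on every
    usable scan of the target site; deterministic.
few_shot : augment the source-site training set with both scans of
    ``n_target`` randomly drawn target-site subjects; test on the remaining
    target-site scans.  Repeated with fresh subject draws.

Splitting is always at the subject level: a participant never contributes
scans to both sides.  The PCA projection (95% retained train variance) and,
for the tangent measure, the reference mean are fitted on training scans
only; both record the scan ids they saw, so leakage is machine-checkable.

Scan selection: at the three-session site each subject contributes the EO
scan and the session-1 EC scan, so a 48-subject source yields 96 training
samples; two-session subjects contribute both scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .connectivity import TangentReference, fit_tangent_reference, fc_matrix, vectorize

POSITIVE_STATE = "EO"  # label 1 throughout the package


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    protocol: str
    seed: int | None = None
    n_target_subjects: int | None = None


@dataclass
class FittedModel:
    """PCA projection + L2 logistic regression with train provenance."""

    pca: PCA
    clf: LogisticRegression
    train_scan_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Variances of the retained principal components (lambda)."""
        return self.pca.explained_variance_

    @property
    def components(self) -> np.ndarray:
        """(n_components, n_edges) projection matrix V^T."""
        return self.pca.components_

    @property
    def weights_pca(self) -> np.ndarray:
        return self.clf.coef_.ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(self.pca.transform(X))[:, 1]


@dataclass
class EvalResult:
    scan_ids: tuple[str, ...]
    subjects: tuple[str, ...]
    y_true: np.ndarray
    proba: np.ndarray
    accuracy: float
    roc_auc: float
    brier_per_scan: np.ndarray
    brier_per_subject: pd.Series


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def select_classification_scans(manifest: pd.DataFrame) -> pd.DataFrame:
    """One EO and one EC scan per subject.

    Subjects with three sessions keep their EO scan and the session-1 EC
    scan; two-session subjects keep both scans unchanged.
    """
    keep = []
    for _, grp in manifest.groupby("subject", sort=False):
        if len(grp) <= 2:
            keep.append(grp)
            continue
        eo = grp[grp.state == "EO"]
        ec1 = grp[(grp.state == "EC") & (grp.session == grp[grp.state == "EC"].session.min())]
        keep.append(pd.concat([ec1, eo]))
    return pd.concat(keep).sort_index().reset_index(drop=True)


def make_split(manifest: pd.DataFrame, protocol: str, source_site: str,
               target_site: str, n_target: int | None = None,
               seed: int = 0) -> SplitPlan:
    """Subject-level split for one protocol run (see module docstring)."""
    mf = select_classification_scans(manifest)
    src = mf[mf.site == source_site]
    tgt = mf[mf.site == target_site]
    if src.empty or tgt.empty:
        raise ValueError("manifest must cover both sites")
    if protocol == "cross_site":
        return SplitPlan(tuple(src.scan_id), tuple(tgt.scan_id), "cross_site")
    if protocol != "few_shot":
        raise ValueError(f"unknown protocol {protocol!r}")
    subjects = tgt.subject.unique()
    if n_target is None or n_target < 1:
        raise ValueError("few_shot requires n_target >= 1")
    if n_target >= len(subjects):
        raise ValueError(
            f"n_target={n_target} must be below the {len(subjects)} "
            "target-site subjects")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(subjects, size=n_target, replace=False))
    train = pd.concat([src, tgt[tgt.subject.isin(chosen)]])
    test = tgt[~tgt.subject.isin(chosen)]
    return SplitPlan(tuple(train.scan_id), tuple(test.scan_id), "few_shot",
                     seed, n_target)


def assert_no_subject_leakage(split: SplitPlan, manifest: pd.DataFrame) -> None:
    sub = manifest.set_index("scan_id").subject
    train_subjects = set(sub.loc[list(split.train_ids)])
    test_subjects = set(sub.loc[list(split.test_ids)])
    overlap = train_subjects & test_subjects
    if overlap:
        raise AssertionError(f"subjects span train and test: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# Model fit / evaluation
# ---------------------------------------------------------------------------

def fit_model(X: np.ndarray, y: np.ndarray,
              train_scan_ids: Sequence[str] = (),
              explained_variance: float = 0.95,
              C: float = 1.0) -> FittedModel:
    """PCA at 95% train variance, then L2 logistic regression (C=1, LBFGS)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    pca = PCA(n_components=explained_variance, svd_solver="full").fit(X)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    clf.fit(pca.transform(X), y)
    return FittedModel(pca, clf, tuple(train_scan_ids))


def roc_auc_rank(y_true: np.ndarray, proba: np.ndarray) -> float:
    """ROC-AUC as the Mann-Whitney rank statistic with average-rank ties."""
    y = np.asarray(y_true).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(proba)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(model: FittedModel, X: np.ndarray, y: np.ndarray,
             scan_ids: Sequence[str], subjects: Sequence[str]) -> EvalResult:
    """Accuracy at the 0.5 threshold, rank ROC-AUC and per-scan Brier loss."""
    y = np.asarray(y).astype(int)
    proba = model.predict_proba(np.asarray(X, dtype=float))
    acc = float(((proba >= 0.5).astype(int) == y).mean())
    brier = (proba - y) ** 2
    per_subject = pd.Series(brier, index=pd.Index(subjects, name="subject"))
    return EvalResult(tuple(scan_ids), tuple(subjects), y, proba, acc,
                      roc_auc_rank(y, proba), brier,
                      per_subject.groupby(level=0).mean())


# ---------------------------------------------------------------------------
# Protocol runner
# ---------------------------------------------------------------------------

def _features_for(covs: Mapping[str, np.ndarray], ids: Sequence[str],
                  measure: str, tangent_ref: TangentReference | None,
                  glasso_alpha: float,
                  region_subset: np.ndarray | None) -> np.ndarray:
    rows = []
    for sid in ids:
        cov = covs[sid]
        if region_subset is not None:
            cov = cov[np.ix_(region_subset, region_subset)]
        rows.append(vectorize(fc_matrix(cov, measure, tangent_ref,
                                        glasso_alpha)))
    return np.vstack(rows)


def run_split(covs: Mapping[str, np.ndarray], manifest: pd.DataFrame,
              split: SplitPlan, measure: str, glasso_alpha: float = 0.05,
              region_subset: np.ndarray | None = None,
              ) -> tuple[EvalResult, FittedModel, TangentReference | None]:
    """Fit and evaluate one split; tangent reference fitted on train only."""
    assert_no_subject_leakage(split, manifest)
    info = manifest.set_index("scan_id")
    ref = None
    if measure == "tangent":
        train_covs = [covs[sid] if region_subset is None
                      else covs[sid][np.ix_(region_subset, region_subset)]
                      for sid in split.train_ids]
        ref = fit_tangent_reference(train_covs, tuple(split.train_ids))
    Xtr = _features_for(covs, split.train_ids, measure, ref, glasso_alpha,
                        region_subset)
    ytr = (info.loc[list(split.train_ids)].state == POSITIVE_STATE).to_numpy(int)
    model = fit_model(Xtr, ytr, split.train_ids)
    Xte = _features_for(covs, split.test_ids, measure, ref, glasso_alpha,
                        region_subset)
    yte = (info.loc[list(split.test_ids)].state == POSITIVE_STATE).to_numpy(int)
    result = evaluate(model, Xte, yte, split.test_ids,
                      info.loc[list(split.test_ids)].subject)
    return result, model, ref


def run_protocol(covs: Mapping[str, np.ndarray], manifest: pd.DataFrame,
                 measure: str, protocol: str, source_site: str = "site_B",
                 target_site: str = "site_A", n_target: int | None = None,
                 n_iterations: int = 15, base_seed: int = 0,
                 glasso_alpha: float = 0.05,
                 region_subset: np.ndarray | None = None) -> list[EvalResult]:
    """Run a protocol end to end; few_shot repeats with seeds base_seed + i."""
    results = []
    if protocol == "cross_site":
        for src, tgt in ((source_site, target_site), (target_site, source_site)):
            split = make_split(manifest, "cross_site", src, tgt)
            res, _, _ = run_split(covs, manifest, split, measure,
                                  glasso_alpha, region_subset)
            results.append(res)
        return results
    if protocol != "few_shot":
        raise ValueError(f"unknown protocol {protocol!r}")
    for i in range(n_iterations):
        split = make_split(manifest, "few_shot", source_site, target_site,
                           n_target=n_target, seed=base_seed + i)
        res, _, _ = run_split(covs, manifest, split, measure,
                              glasso_alpha, region_subset)
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Benchmark grid
# ---------------------------------------------------------------------------

MEASURES = ("pearson", "partial", "glasso", "tangent")


def grid_cells(strategy_ids: Sequence[int], measures: Sequence[str],
               parcellations: Sequence[str]) -> list[dict]:
    """Enumerate the pipeline grid: one cell per (strategy, measure, atlas)."""
    return [
        {"strategy": s, "measure": m, "parcellation": p,
         "cell_id": f"s{s:02d}_{m}_{p}"}
        for s, m, p in product(strategy_ids, measures, parcellations)
    ]


def run_grid(covs_per_strategy: Mapping[int, Mapping[str, np.ndarray]],
             manifest: pd.DataFrame, cells: Sequence[dict],
             region_subsets: Mapping[str, np.ndarray | None],
             protocol: str = "cross_site", glasso_alpha: float = 0.05,
             **protocol_kwargs) -> pd.DataFrame:
    """Execute the grid cell by cell, recording partial failures.

    Returns one row per (cell, protocol run) with accuracy, ROC-AUC and the
    per-subject Brier table attached; failed cells carry the error message
    and NaN metrics so the grid always completes.
    """
    rows = []
    for cell in cells:
        try:
            results = run_protocol(
                covs_per_strategy[cell["strategy"]], manifest,
                cell["measure"], protocol,
                glasso_alpha=glasso_alpha,
                region_subset=region_subsets[cell["parcellation"]],
                **protocol_kwargs)
        except Exception as exc:  # noqa: BLE001 - grid must keep going
            rows.append({**cell, "run": 0, "direction": None,
                         "accuracy": np.nan, "roc_auc": np.nan,
                         "brier_mean": np.nan, "error": str(exc),
                         "brier_per_subject": None})
            continue
        for i, res in enumerate(results):
            direction = None
            if protocol == "cross_site":
                direction = ("site_B->site_A", "site_A->site_B")[i]
            rows.append({**cell, "run": i, "direction": direction,
                         "accuracy": res.accuracy, "roc_auc": res.roc_auc,
                         "brier_mean": float(res.brier_per_scan.mean()),
                         "error": "",
                         "brier_per_subject": res.brier_per_subject})
    return pd.DataFrame(rows)
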