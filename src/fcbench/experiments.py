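"""End-to-end experiment drivers tying the modules together.

Everything the numbered analysis scripts and the acceptance checks compute
lives here so it is importable and testable.  Desk-scale defaults (20 + 12
subjects, 20 regions, 5 planted edges) are the package's study conditions;
the full-size two-site geometry is available through ``size="full"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, denoise, factor_stats, qc, stability, synthetic
from .connectivity import (estimate_covariance, fc_matrix,
                           fit_tangent_reference, vectorize)

DESK_N_REGIONS = 20
DESK_N_DIFF_EDGES = 5
DESK_EFFECT_SIZE = 0.3


@dataclass
class SimulatedStudy:
    """A simulated two-site study and its derived per-scan quantities."""

    gt: synthetic.GroundTruth
    dataset: list[tuple[synthetic.ScanRecord, synthetic.ConfoundTable]]
    manifest: pd.DataFrame
    motion: pd.Series = field(default_factory=pd.Series)  # scan_id -> mean RMSD

    def confounds_by_scan(self) -> dict[str, synthetic.ConfoundTable]:
        return {scan.scan_id: conf for scan, conf in self.dataset}


def build_study(seed: int = 0, size: str = "desk",
                n_regions: int = DESK_N_REGIONS,
                n_diff_edges: int = DESK_N_DIFF_EDGES,
                effect_size: float = DESK_EFFECT_SIZE,
                **dataset_kwargs) -> SimulatedStudy:
    """Ground truth + simulated dataset + manifest + per-scan motion scalars."""
    gt = synthetic.make_ground_truth(n_regions, n_diff_edges, effect_size,
                                     seed=seed)
    dataset = synthetic.simulate_dataset(gt, seed=seed + 1, size=size,
                                         **dataset_kwargs)
    manifest = synthetic.manifest_frame(dataset)
    motion = pd.Series({scan.scan_id: qc.mean_relative_rmsd(conf.motion())
                        for scan, conf in dataset})
    return SimulatedStudy(gt, dataset, manifest, motion)


def clean_study(study: SimulatedStudy, strategy_ids=(1,)) -> dict[int, dict[str, np.ndarray]]:
    """Denoise every scan under each strategy: {strategy: {scan_id: T x R}}."""
    out: dict[int, dict[str, np.ndarray]] = {}
    for sid in strategy_ids:
        spec = denoise.get_strategy(sid)
        out[sid] = {scan.scan_id: denoise.clean_scan(spec, scan.timeseries, conf)
                    for scan, conf in study.dataset}
    return out


def covariances(cleaned: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {sid: estimate_covariance(Y) for sid, Y in cleaned.items()}


def edge_table(covs: dict[str, np.ndarray], scan_ids, measure: str,
               tangent_ref=None, glasso_alpha: float = 0.05) -> np.ndarray:
    """Stack edge vectors for the given scans in order."""
    return np.vstack([
        vectorize(fc_matrix(covs[sid], measure, tangent_ref, glasso_alpha))
        for sid in scan_ids])


# ---------------------------------------------------------------------------
# QC-FC ordering experiment
# ---------------------------------------------------------------------------

def qcfc_denoising_comparison(study: SimulatedStudy, site: str = "site_B",
                              state: str = "EC") -> dict[str, float]:
    """QC-FC under no denoising, 24HMP, and oracle regression.

    The oracle design contains exactly the nuisance series the generator
    injected: the motion block and the latent physiological components.
    Computed per (site, state) cell on Pearson FC: one scan per subject.
    """
    mf = study.manifest
    sel = mf[(mf.site == site) & (mf.state == state)]
    sel = sel.sort_values(["subject", "session"]).groupby("subject").head(1)
    confs = study.confounds_by_scan()
    scans = {scan.scan_id: scan for scan, _ in study.dataset}

    def edges_under(clean_fn) -> np.ndarray:
        rows = []
        for sid in sel.scan_id:
            Y = clean_fn(scans[sid].timeseries, confs[sid])
            cov = estimate_covariance(Y)
            rows.append(vectorize(fc_matrix(cov, "pearson")))
        return np.vstack(rows)

    def none_clean(Y, conf):
        T = Y.shape[0]
        return denoise.residualize(Y, np.ones((T, 1)))

    def hmp24_clean(Y, conf):
        return denoise.clean_scan(denoise.get_strategy(1), Y, conf)

    def oracle_clean(Y, conf):
        X = np.column_stack([
            np.ones(Y.shape[0]),
            denoise.expand_motion(conf.motion(), "HMP24").to_numpy(),
            conf.latent_components(),
        ])
        return denoise.residualize(Y, X)

    motion = study.motion.loc[sel.scan_id].to_numpy()
    out = {}
    for name, fn in (("no_denoise", none_clean), ("hmp24", hmp24_clean),
                     ("oracle", oracle_clean)):
        _, score = qc.qcfc(edges_under(fn), motion)
        out[name] = score
    return out


# ---------------------------------------------------------------------------
# ICC masking experiment
# ---------------------------------------------------------------------------

def icc_masking_comparison(study: SimulatedStudy, strategy_id: int = 3,
                           measure: str = "glasso",
                           percentile: float = 95.0) -> dict[str, float]:
    """Mean per-edge ICC(3,1) between repeated EC scans, masked vs unmasked.

    Uses the three-session site, pairing each subject's first EC scan with
    the later one (raters k=2).  Sparse measures (glasso) have many null
    edges whose ICC clusters near zero; masking to the strongest 5% of
    |group-mean| edges removes them.
    """
    mf = study.manifest
    site_b = mf[(mf.site == "site_B") & (mf.state == "EC")]
    cleaned = clean_study(study, (strategy_id,))[strategy_id]
    covs = covariances(cleaned)

    pairs = []
    for _, grp in site_b.groupby("subject"):
        grp = grp.sort_values("session")
        if len(grp) >= 2:
            pairs.append((grp.scan_id.iloc[0], grp.scan_id.iloc[1]))
    first = edge_table(covs, [a for a, _ in pairs], measure)
    second = edge_table(covs, [b for _, b in pairs], measure)

    E = first.shape[1]
    icc_vals = np.full(E, np.nan)
    for e in range(E):
        table = np.column_stack([first[:, e], second[:, e]])
        try:
            icc_vals[e] = qc.icc(table).icc31
        except ValueError:
            continue  # zero-variance edge: ICC undefined, left out
    group_mean = np.vstack([first, second]).mean(axis=0)
    mask = qc.mask_edges(group_mean, percentile=percentile)
    return {
        "unmasked_mean": float(np.nanmean(icc_vals)),
        "masked_mean": float(np.nanmean(icc_vals[mask])),
        "n_edges": E,
        "n_masked": int(mask.sum()),
    }


# ---------------------------------------------------------------------------
# State-separation experiment
# ---------------------------------------------------------------------------

def state_separation(study: SimulatedStudy, strategy_id: int = 3,
                     measures=("tangent", "partial")) -> dict[str, float]:
    """Within-subject EO/EC dissimilarity per FC measure (scale-free).

    For each subject, the Pearson correlation between the EO and EC edge
    vectors is computed (the same construction as the strategy-similarity
    matrices); separation = 1 - mean correlation.  Larger means the two
    states are further apart in that representation.
    """
    cleaned = clean_study(study, (strategy_id,))[strategy_id]
    covs = covariances(cleaned)
    mf = classify.select_classification_scans(study.manifest).reset_index(drop=True)
    out = {}
    for measure in measures:
        ref = None
        if measure == "tangent":
            ref = fit_tangent_reference([covs[s] for s in mf.scan_id],
                                        tuple(mf.scan_id))
        X = edge_table(covs, mf.scan_id, measure, tangent_ref=ref)
        corrs = []
        for _, grp in mf.groupby("subject"):
            eo = grp[grp.state == "EO"].index[0]
            ec = grp[grp.state == "EC"].index[0]
            corrs.append(np.corrcoef(X[eo], X[ec])[0, 1])
        out[measure] = float(1.0 - np.mean(corrs))
    return out


# ---------------------------------------------------------------------------
# Classification experiments
# ---------------------------------------------------------------------------

def classification_experiment(study: SimulatedStudy, strategy_id: int = 3,
                              measure: str = "tangent",
                              n_target: int = 5, n_iterations: int = 15,
                              seed: int = 0) -> dict[str, float]:
    """Cross-site (both directions) + few-shot protocol on one pipeline."""
    cleaned = clean_study(study, (strategy_id,))[strategy_id]
    covs = covariances(cleaned)
    cross = classify.run_protocol(covs, study.manifest, measure, "cross_site")
    few = classify.run_protocol(covs, study.manifest, measure, "few_shot",
                                n_target=n_target, n_iterations=n_iterations,
                                base_seed=seed)
    return {
        "cross_site_accuracy": float(np.mean([r.accuracy for r in cross])),
        "cross_site_auc": float(np.mean([r.roc_auc for r in cross])),
        "few_shot_accuracy_mean": float(np.mean([r.accuracy for r in few])),
        "few_shot_accuracy_std": float(np.std([r.accuracy for r in few])),
        "n_test_scans": len(few[0].scan_ids),
    }


def null_calibration_experiment(seed: int = 0, n_iterations: int = 15,
                                n_target: int = 5) -> dict[str, float]:
    """Few-shot accuracy on a zero-effect study (EO and EC identical).

    Returns the mean accuracy and the half-width of the binomial 95% band
    around 0.5 for a single iteration's test-set size (iterations share
    test subjects, so one iteration is the conservative effective n).
    """
    study = build_study(seed=seed, n_diff_edges=0, effect_size=0.0)
    cleaned = clean_study(study, (3,))[3]
    covs = covariances(cleaned)
    few = classify.run_protocol(covs, study.manifest, "pearson", "few_shot",
                                n_target=n_target, n_iterations=n_iterations,
                                base_seed=seed)
    n_test = len(few[0].scan_ids)
    return {
        "accuracy_mean": float(np.mean([r.accuracy for r in few])),
        "band_half_width": float(1.96 * np.sqrt(0.25 / n_test)),
        "n_test": n_test,
    }


# ---------------------------------------------------------------------------
# Stability recovery experiment
# ---------------------------------------------------------------------------

def stability_recovery(study: SimulatedStudy, strategy_id: int = 3,
                       measure: str = "pearson", n_iterations: int = 100,
                       seed: int = 0) -> dict[str, float]:
    """Precision/recall of the stable-edge set against the planted edges."""
    cleaned = clean_study(study, (strategy_id,))[strategy_id]
    covs = covariances(cleaned)
    mf = classify.select_classification_scans(study.manifest)
    ref = None
    if measure == "tangent":
        ref = fit_tangent_reference([covs[s] for s in mf.scan_id],
                                    tuple(mf.scan_id))
    X = edge_table(covs, mf.scan_id, measure, tangent_ref=ref)
    report = stability.stability_run(X, mf, n_iterations=n_iterations,
                                     seed=seed)
    stable = stability.stable_edges(report)
    from .connectivity import edge_index_map
    index_map = {pair: idx for idx, pair in
                 enumerate(edge_index_map(study.gt.n_regions))}
    truth = {index_map[(i, j)] for i, j, _ in study.gt.diff_edges}
    found = set(stable.index)
    tp = len(truth & found)
    return {
        "precision": tp / len(found) if found else 0.0,
        "recall": tp / len(truth) if truth else 0.0,
        "n_stable": len(found),
        "n_planted": len(truth),
        "k": report.k,
    }


# ---------------------------------------------------------------------------
# Sign-flip type-I calibration
# ---------------------------------------------------------------------------

def sign_flip_type_i(n_replicates: int = 1000, n_subjects: int = 20,
                     n_perm: int = 1000, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Rejection rate of the sign-flip test under a symmetric null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_replicates):
        diffs = rng.standard_normal(n_subjects)
        res = factor_stats.sign_flip_test(diffs, n_perm=n_perm,
                                          seed=seed + rep + 1)
        rejections += res.p_value <= alpha
    return rejections / n_replicates
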