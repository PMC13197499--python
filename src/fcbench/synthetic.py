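"""Synthetic two-site eyes-open / eyes-closed dataset with known ground truth.

The generator emulates the study design the benchmark is built around: one
site with longer-TR, shorter scans and two sessions per subject (EO, EC),
and a second site with shorter-TR, longer scans and three sessions (EC
first, then EO/EC counterbalanced by subject parity).  Brain-state structure
is planted as a covariance difference on a known subset of edges; head
motion enters the signal as a coupled random walk, and latent physiological
components mirror the fMRIPrep confound columns so every denoising strategy
has something real to remove.

Signal model for one scan (T volumes, R regions):

    y_t = scale * ( L z_t  +  c * w m_t  +  c * a_s * Lambda x_t  +  eps_t )

where L is a Cholesky factor of the state covariance (plus a rank-one
subject effect), z_t is a unit-variance AR(1) latent draw, m_t the mean
frame-to-frame motion increment, w the per-region motion-coupling weights,
x_t the latent physiological components with loadings Lambda, eps_t white
noise, c the coupling strength and a_s the subject's motion amplitude
relative to the cohort reference.  Scaling physiological coupling by a_s
makes high-motion subjects also high-artifact subjects, which is what makes
QC-FC respond to component regression the way it does on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import qc
from .denoise import cosine_basis

SITES = ("site_A", "site_B")
STATES = ("EO", "EC")

#: reference motion amplitude (mm) that coupling terms are normalized to
AMPLITUDE_REF = 0.1


@dataclass(frozen=True)
class SiteParams:
    """Acquisition geometry of one site."""

    tr: float          # seconds
    n_volumes: int
    n_subjects: int    # full-size subject count
    scale: float = 1.0  # global signal-amplitude factor (site effect)


DEFAULT_SITE_PARAMS = {
    "site_A": SiteParams(tr=2.5, n_volumes=120, n_subjects=84, scale=1.0),
    "site_B": SiteParams(tr=2.0, n_volumes=240, n_subjects=48, scale=1.2),
}

#: scaled-down subject counts for desk-scale runs
DESK_SUBJECTS = {"site_A": 20, "site_B": 12}


@dataclass
class GroundTruth:
    """Planted population structure shared by all simulated scans."""

    n_regions: int
    cov_eo: np.ndarray
    cov_ec: np.ndarray
    diff_edges: list[tuple[int, int, float]]  # (i, j, signed delta)
    motion_coupling: np.ndarray               # (R,)
    component_loadings: np.ndarray            # (R, n_latent)
    site_params: dict[str, SiteParams] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PARAMS))
    spd_shift: dict[str, float] = field(default_factory=dict)

    def state_cov(self, state: str) -> np.ndarray:
        if state == "EO":
            return self.cov_eo
        if state == "EC":
            return self.cov_ec
        raise ValueError(f"state must be one of {STATES}, got {state!r}")


def _ar1(rng: np.random.Generator, T: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series."""
    e = rng.standard_normal(T)
    x = lfilter([1.0], [1.0, -phi], e * np.sqrt(1 - phi**2))
    x[0] = e[0]  # start from the stationary marginal
    return x


def make_ground_truth(n_regions: int, n_diff_edges: int = 5,
                      effect_size: float = 0.3, seed: int = 0,
                      n_factors: int = 3, n_latent: int = 13,
                      site_params: dict[str, SiteParams] | None = None,
                      eps: float = 1e-6) -> GroundTruth:
    """Build the population ground truth with planted differential edges.

    The base covariance is a 3-factor model normalized to unit diagonal
    (a correlation-like SPD matrix).  ``n_diff_edges`` upper-triangle
    entries of the EC covariance are shifted by ``effect_size`` with
    alternating sign; if restoring positive definiteness would require a
    diagonal shift of 10% of the effect size or more, the configuration is
    rejected with an explicit error naming the minimum eigenvalue.
    """
    R = int(n_regions)
    if R < 4:
        raise ValueError("need at least 4 regions")
    max_edges = R * (R - 1) // 2
    if not 0 <= n_diff_edges <= max_edges:
        raise ValueError(f"n_diff_edges must be in [0, {max_edges}]")
    rng = np.random.default_rng(seed)

    W = 0.8 * rng.standard_normal((R, n_factors))
    C = W @ W.T + np.diag(rng.uniform(1.0, 2.0, size=R))
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)

    # Plant differential edges on node-disjoint pairs with weak baseline
    # correlation: the perturbation then has spectral norm = |effect_size|
    # and no entry leaves the plausible correlation range.
    iu, ju = np.triu_indices(R, k=1)
    order = rng.permutation(max_edges)
    used_nodes: set[int] = set()
    chosen: list[tuple[int, int]] = []
    for e in order:
        if len(chosen) == n_diff_edges:
            break
        i, j = int(iu[e]), int(ju[e])
        if i in used_nodes or j in used_nodes:
            continue
        if abs(C[i, j]) + abs(effect_size) > 0.75:
            continue
        chosen.append((i, j))
        used_nodes.update((i, j))
    if len(chosen) < n_diff_edges:
        raise ValueError(
            f"could not place {n_diff_edges} node-disjoint differential edges "
            f"with effect size {effect_size} on {R} regions")
    diff_edges = []
    delta = np.zeros((R, R))
    for rank, (i, j) in enumerate(sorted(chosen)):
        sgn = 1.0 if rank % 2 == 0 else -1.0
        diff_edges.append((i, j, sgn * effect_size))
        delta[i, j] = delta[j, i] = sgn * effect_size

    cov_eo = C.copy()
    cov_ec = C + delta
    shifts = {}
    for name, cov in (("EO", cov_eo), ("EC", cov_ec)):
        lam_min = float(np.linalg.eigvalsh(cov)[0])
        tau = max(0.0, eps - lam_min)
        if n_diff_edges > 0 and effect_size != 0 and tau >= 0.1 * abs(effect_size):
            raise ValueError(
                f"effect size {effect_size} infeasible: {name} covariance has "
                f"minimum eigenvalue {lam_min:.4g}, SPD repair (tau={tau:.4g}) "
                "would dominate the planted effect")
        if tau > 0:
            cov += tau * np.eye(R)
            shifts[name] = tau

    return GroundTruth(
        n_regions=R,
        cov_eo=cov_eo,
        cov_ec=cov_ec,
        diff_edges=diff_edges,
        motion_coupling=rng.standard_normal(R),
        component_loadings=rng.standard_normal((R, n_latent)) / np.sqrt(n_latent),
        site_params=dict(site_params or DEFAULT_SITE_PARAMS),
        spd_shift=shifts,
    )


# ---------------------------------------------------------------------------
# Confounds
# ---------------------------------------------------------------------------

@dataclass
class ConfoundTable:
    """fMRIPrep-style confound table plus per-component metadata."""

    data: pd.DataFrame
    acompcor_shares: np.ndarray
    aroma_noise_flags: np.ndarray

    def __len__(self) -> int:
        return len(self.data)

    def columns_matching(self, prefix: str) -> list[str]:
        return [c for c in self.data.columns if c.startswith(prefix)]

    def motion(self) -> pd.DataFrame:
        return self.data.loc[:, list(qc.MOTION_COLUMNS)]

    def latent_components(self) -> np.ndarray:
        """aCompCor then tCompCor columns: the injected physiological noise."""
        cols = self.columns_matching("a_comp_cor_") + self.columns_matching("t_comp_cor_")
        return self.data[cols].to_numpy(dtype=float)


def simulate_confounds(T: int, tr: float, motion_amplitude: float = 0.1,
                       n_acompcor: int = 10, n_aroma: int = 6,
                       seed: int = 0, n_tcompcor: int = 3,
                       ar_phi: float = 0.3) -> ConfoundTable:
    """Simulate one scan's confound table.

    Motion columns are random walks with AR(1) increments scaled to
    ``motion_amplitude`` (mm for translations; rotations get amplitude/100
    rad so both families contribute comparably to FD).  Component columns
    are unit-variance AR(1) series; aCompCor explained-variance shares decay
    geometrically.  Framewise displacement and relative RMSD are computed
    from the motion columns by :mod:`fcbench.qc` - single source of truth.
    """
    if T < 30:
        raise ValueError("need T >= 30 volumes")
    if motion_amplitude < 0:
        raise ValueError("motion_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}

    scales = [motion_amplitude] * 3 + [motion_amplitude / 100.0] * 3
    for name, s in zip(qc.MOTION_COLUMNS, scales):
        inc = _ar1(rng, T, ar_phi) * s
        cols[name] = np.cumsum(inc)

    motion = pd.DataFrame({c: cols[c] for c in qc.MOTION_COLUMNS})
    inc = np.zeros((T, 6))
    inc[1:] = np.diff(motion.to_numpy(), axis=0)

    gs = _ar1(rng, T, ar_phi)
    step = np.abs(inc[:, :3]).sum(axis=1)
    if step.std() > 0:
        gs = gs + 0.5 * (step - step.mean()) / step.std()
    cols["global_signal"] = gs

    r = 0.65
    shares = 0.8 * (1 - r) * r ** np.arange(n_acompcor)
    for i in range(n_acompcor):
        cols[f"a_comp_cor_{i:02d}"] = _ar1(rng, T, ar_phi)
    for i in range(n_tcompcor):
        cols[f"t_comp_cor_{i:02d}"] = _ar1(rng, T, ar_phi)

    n_noise = max(1, int(round(0.6 * n_aroma))) if n_aroma else 0
    flags = np.zeros(n_aroma, dtype=bool)
    flags[:n_noise] = True
    for i in range(n_aroma):
        if flags[i]:
            mix = inc[:, i % 6]
            sd = mix.std()
            base = mix / sd if sd > 0 else np.zeros(T)
            cols[f"aroma_motion_{i:02d}"] = 0.8 * base + 0.2 * _ar1(rng, T, ar_phi)
        else:
            cols[f"aroma_motion_{i:02d}"] = _ar1(rng, T, ar_phi)

    drift = cosine_basis(T, tr).reset_index(drop=True)
    tail = pd.DataFrame({
        "framewise_displacement": qc.framewise_displacement(motion),
        "rmsd": qc.relative_rmsd(motion),
    })
    frame = pd.concat([pd.DataFrame(cols), drift, tail], axis=1)
    return ConfoundTable(frame, shares, flags)


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

@dataclass
class ScanRecord:
    """One scan's ROI time series plus identifiers."""

    subject_id: str
    site: str
    state: str
    session: int
    timeseries: np.ndarray  # T x R
    tr: float

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2 or ts.shape[0] < 30:
            raise ValueError("timeseries must be T x R with T >= 30")
        if not np.isfinite(ts).all():
            raise ValueError("non-finite values in timeseries")
        self.timeseries = ts

    @property
    def scan_id(self) -> str:
        return f"{self.subject_id}_ses-{self.session}_{self.state}"


def motion_increment_summary(confounds: ConfoundTable) -> np.ndarray:
    """Per-volume mean motion increment (mm), the quantity coupled into signal."""
    arr = confounds.motion().to_numpy(dtype=float)
    inc = np.zeros_like(arr)
    inc[1:] = np.diff(arr, axis=0)
    return inc[:, :3].mean(axis=1) + 100.0 * inc[:, 3:].mean(axis=1)


def simulate_scan(gt: GroundTruth, confounds: ConfoundTable, state: str,
                  site: str, coupling_strength: float = 1.0, seed: int = 0,
                  noise_sigma: float = 0.05,
                  subject_effect: np.ndarray | None = None,
                  subject_effect_scale: float = 0.1,
                  ar_phi: float = 0.3) -> ScanRecord:
    """Draw one scan from the signal model in the module docstring.

    ``subject_effect`` is the per-subject vector u_s; the scan covariance is
    cov_state + subject_effect_scale * u_s u_s', giving stable
    between-subject differences (the variance component ICC measures).
    """
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}")
    if site not in SITES:
        raise ValueError(f"site must be one of {SITES}")
    rng = np.random.default_rng(seed)
    R = gt.n_regions
    T = len(confounds)
    cov = gt.state_cov(state)
    if subject_effect is not None:
        u = np.asarray(subject_effect, dtype=float)
        cov = cov + subject_effect_scale * np.outer(u, u)
    L = np.linalg.cholesky(cov)

    z = np.column_stack([_ar1(rng, T, ar_phi) for _ in range(R)])
    y = z @ L.T

    if coupling_strength != 0:
        m = motion_increment_summary(confounds) / AMPLITUDE_REF
        y = y + coupling_strength * np.outer(m, gt.motion_coupling)
        amp_hat = m.std()
        comps = confounds.latent_components()
        n_latent = min(comps.shape[1], gt.component_loadings.shape[1])
        if n_latent and amp_hat > 0:
            y = y + coupling_strength * amp_hat * (
                comps[:, :n_latent] @ gt.component_loadings[:, :n_latent].T)

    if noise_sigma > 0:
        y = y + noise_sigma * rng.standard_normal((T, R))
    y = y * gt.site_params[site].scale
    return ScanRecord("sub-anon", site, state, 1, y, gt.site_params[site].tr)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _site_sessions(site: str, subject_index: int) -> list[tuple[int, str]]:
    """Session schedule: (session number, state) pairs for one subject."""
    if site == "site_A":
        return [(1, "EC"), (2, "EO")]
    # site_B: first session always EC; sessions 2-3 counterbalanced by parity
    if subject_index % 2 == 0:
        return [(1, "EC"), (2, "EO"), (3, "EC")]
    return [(1, "EC"), (2, "EC"), (3, "EO")]


def design_manifest(gt: GroundTruth, size: str = "desk") -> pd.DataFrame:
    """Scan manifest (subject, site, state, session) without simulating data."""
    rows = []
    for site in SITES:
        n = _subject_count(gt, site, size)
        for s in range(n):
            subject = f"sub-{site[-1]}{s:03d}"
            for session, state in _site_sessions(site, s):
                rows.append({
                    "scan_id": f"{subject}_ses-{session}_{state}",
                    "subject": subject, "site": site,
                    "state": state, "session": session,
                })
    return pd.DataFrame(rows)


def _subject_count(gt: GroundTruth, site: str, size: str) -> int:
    if size == "full":
        return gt.site_params[site].n_subjects
    if size == "desk":
        return DESK_SUBJECTS[site]
    raise ValueError(f"size must be 'desk' or 'full', got {size!r}")


def simulate_dataset(gt: GroundTruth, seed: int = 0, size: str = "desk",
                     coupling_strength: float = 1.0,
                     motion_amplitude_mean: float = 0.1,
                     noise_sigma: float = 0.05,
                     subject_effect_scale: float = 0.1,
                     ) -> list[tuple[ScanRecord, ConfoundTable]]:
    """Simulate the full two-site dataset.

    Subject motion amplitudes are log-normal around ``motion_amplitude_mean``
    (sigma 0.4 on the log scale), so motion contamination varies across
    subjects the way QC-FC needs it to.  Each subject carries a fixed random
    effect u_s across all their scans.
    """
    out: list[tuple[ScanRecord, ConfoundTable]] = []
    for site in SITES:
        params = gt.site_params[site]
        n = _subject_count(gt, site, size)
        for s in range(n):
            subject = f"sub-{site[-1]}{s:03d}"
            subj_rng = np.random.default_rng(
                np.random.SeedSequence((seed, SITES.index(site), s)))
            amplitude = motion_amplitude_mean * float(
                np.exp(subj_rng.normal(0.0, 0.4)))
            u = subj_rng.standard_normal(gt.n_regions)
            for session, state in _site_sessions(site, s):
                child = np.random.SeedSequence(
                    (seed, SITES.index(site), s, session))
                seeds = child.generate_state(2)
                conf = simulate_confounds(params.n_volumes, params.tr,
                                          motion_amplitude=amplitude,
                                          seed=int(seeds[0]))
                scan = simulate_scan(gt, conf, state, site,
                                     coupling_strength=coupling_strength,
                                     seed=int(seeds[1]),
                                     noise_sigma=noise_sigma,
                                     subject_effect=u,
                                     subject_effect_scale=subject_effect_scale)
                scan.subject_id = subject
                scan.session = session
                out.append((scan, conf))
    return out


def manifest_frame(dataset: list[tuple[ScanRecord, ConfoundTable]]) -> pd.DataFrame:
    """Manifest table for an already-simulated dataset."""
    rows = [{
        "scan_id": scan.scan_id, "subject": scan.subject_id, "site": scan.site,
        "state": scan.state, "session": scan.session,
    } for scan, _ in dataset]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Label-volume fixture for the coverage module
# ---------------------------------------------------------------------------

def simulate_label_volume(shape: tuple[int, int, int], n_parcels: int,
                          seed: int = 0, n_subjects: int = 4,
                          background_fraction: float = 0.2,
                          low_signal_parcel: int | None = None,
                          low_signal_factor: float = 0.1,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous-block parcellation plus per-subject mean-signal images.

    Returns ``(labels, signals)`` where ``labels`` is an integer 3-D array
    (0 = background, parcels 1..n_parcels as contiguous slabs) and
    ``signals`` has shape (n_subjects, *shape) with positive values.  If
    ``low_signal_parcel`` is set, that parcel's signal is scaled by
    ``low_signal_factor`` in every subject, planting a parcel that the
    coverage filter rejects at default thresholds.
    """
    n_voxels = int(np.prod(shape))
    if n_parcels > n_voxels:
        raise ValueError("more parcels than voxels")
    rng = np.random.default_rng(seed)
    flat = np.zeros(n_voxels, dtype=int)
    n_bg = int(round(background_fraction * n_voxels))
    body = n_voxels - n_bg
    bounds = np.linspace(0, body, n_parcels + 1).astype(int)
    for p in range(n_parcels):
        flat[n_bg + bounds[p]: n_bg + bounds[p + 1]] = p + 1
    labels = flat.reshape(shape)

    signals = 100.0 * (1.0 + 0.05 * rng.standard_normal((n_subjects, *shape)))
    signals = np.abs(signals)
    signals[:, labels == 0] *= 0.01  # faint background, still positive
    if low_signal_parcel is not None:
        signals[:, labels == low_signal_parcel] *= low_signal_factor
    return labels, signals
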