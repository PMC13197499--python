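"""Plain-text writers/readers for simulated datasets and result tables.

ROI time series are tab-separated (volumes x labelled region columns),
confounds use the fMRIPrep-style TSV layout with the exact column names of
:class:`~fcbench.synthetic.ConfoundTable`, and the dataset manifest is a
flat table pointing at both files per scan.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ConfoundTable, ScanRecord


def region_columns(n_regions: int) -> list[str]:
    return [f"region_{i:03d}" for i in range(n_regions)]


def write_timeseries(path: Path, scan: ScanRecord) -> None:
    frame = pd.DataFrame(scan.timeseries,
                         columns=region_columns(scan.timeseries.shape[1]))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_timeseries(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_confounds(path: Path, conf: ConfoundTable) -> None:
    conf.data.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {
        "acompcor_shares": conf.acompcor_shares.tolist(),
        "aroma_noise_flags": conf.aroma_noise_flags.astype(bool).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_confounds(path: Path) -> ConfoundTable:
    data = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return ConfoundTable(data, np.asarray(meta["acompcor_shares"]),
                         np.asarray(meta["aroma_noise_flags"], dtype=bool))


def write_dataset(out_dir: Path, dataset, manifest: pd.DataFrame) -> pd.DataFrame:
    """Write every scan + confound table and a manifest with file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    ts_paths, conf_paths = [], []
    for scan, conf in dataset:
        ts = out_dir / f"{scan.scan_id}_timeseries.tsv"
        cf = out_dir / f"{scan.scan_id}_confounds.tsv"
        write_timeseries(ts, scan)
        write_confounds(cf, conf)
        ts_paths.append(ts.name)
        conf_paths.append(cf.name)
    manifest["timeseries_file"] = ts_paths
    manifest["confounds_file"] = conf_paths
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def write_edge_table(path: Path, edge_vector: np.ndarray,
                     index_map: list[tuple[int, int]]) -> None:
    pd.DataFrame({
        "edge": np.arange(len(edge_vector)),
        "region_i": [i for i, _ in index_map],
        "region_j": [j for _, j in index_map],
        "value": edge_vector,
    }).to_csv(path, sep="\t", index=False, float_format="%.8g")
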