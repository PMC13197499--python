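"""Matched-pair factor tests on the classification grid.

Loads the per-cell per-subject Brier tables from the previous step, pairs
pipelines differing in exactly one factor (FC measure, strategy family,
GSR), and runs subject-level sign-flip randomization tests with BH-FDR
within each factor and transfer direction.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from fcbench import factor_stats

FACTORS = ["measure", "family", "gsr"]


def main(seed: int, out_dir: Path, n_perm: int) -> None:
    grid_path = out_dir / "classification_grid.pkl"
    if not grid_path.exists():
        raise SystemExit("run analysis/04_classify.py first")
    with open(grid_path, "rb") as fh:
        table = pickle.load(fh)

    results = []
    for direction, rows in table.groupby("direction"):
        cells = rows[["cell_id"] + FACTORS].drop_duplicates("cell_id")
        briers = {r.cell_id: r.brier_per_subject for r in rows.itertuples()}
        res = factor_stats.run_factor_tests(briers, cells, FACTORS,
                                            n_perm=n_perm, seed=seed)
        res.insert(0, "direction", direction)
        results.append(res)
    out = pd.concat(results, ignore_index=True)
    out.to_csv(out_dir / "factor_comparisons.tsv", sep="\t", index=False)
    n_sig = int(out.significant.sum())
    print(f"{len(out)} factor-level comparisons, {n_sig} significant "
          f"after BH-FDR at alpha=0.05")
    print(out[["direction", "factor", "level_a", "level_b", "delta",
               "p_fdr", "significant"]].to_string(index=False))


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out-dir", type=Path, default=Path("results"))
    p.add_argument("--n-perm", type=int, default=5000)
    a = p.parse_args()
    main(a.seed, a.out_dir, a.n_perm)
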