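"""Receptor-availability PLS against functional group differences.

Reads the PLS tables produced by the pipeline (results/pipeline/pls/):
per-component covariance and Y-variance shares with spin-test p-values,
VIP scores of the two receptor predictors, Spearman correlations between
the component-1 predictor score and each functional response, and
network-averaged predictor scores.

Usage: python analysis/04_receptor_pls.py
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

ROOT = Path(__file__).resolve().parents[1]
PLS = ROOT / "results" / "pipeline" / "pls"


def main() -> None:
    comp = pd.read_csv(PLS / "components.tsv", sep="\t")
    vip = pd.read_csv(PLS / "vip.tsv", sep="\t")
    spearman = pd.read_csv(PLS / "spearman.tsv", sep="\t")
    nets = pd.read_csv(PLS / "network_scores.tsv", sep="\t")
    print("PLS components (share of X'Y cross-covariance / Y variance):")
    for _, row in comp.iterrows():
        print(f"  LV{int(row.component)}: {row.cov_share_pct:.1f}% covariance "
              f"(spin p={row.spin_p_cov:.3f}), {row.y_variance_pct:.1f}% "
              f"Y variance (spin p={row.spin_p_yvar:.3f})")
    print("VIP per receptor predictor (>1 = important):")
    for _, row in vip.iterrows():
        print(f"  {row.predictor}: {row.vip:.2f}")
    print("component-1 predictor score vs functional responses (Spearman):")
    for _, row in spearman.iterrows():
        print(f"  {row.response}: rho={row.rho:+.2f}, p={row.p:.2g}, "
              f"p_spin={row.p_spin:.3f}")
    top = nets.loc[nets.mean_predictor_score.abs().idxmax()]
    print(f"network with largest |mean predictor score|: {top.network} "
          f"({top.mean_predictor_score:+.3f})")


if __name__ == "__main__":
    main()
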