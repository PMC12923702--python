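"""Brain-state dynamics: prevalence and complexity, compared across groups.

Reads the pipeline outputs from analysis/02 (results/pipeline/<task>/
dynamics_*.tsv), prints which metrics differ between groups after max-T
correction, and summarizes the state-probability profile per group.

Usage: python analysis/03_state_dynamics.py
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    for task in ("mid", "cue"):
        tests = pd.read_csv(ROOT / "results" / "pipeline" / task /
                            "dynamics_tests.tsv", sep="\t")
        metrics = pd.read_csv(ROOT / "results" / "pipeline" / task /
                              "dynamics_metrics.tsv", sep="\t")
        sig = tests[tests.significant == 1]
        print(f"{task}: {len(sig)} / {len(tests)} dynamics metrics differ "
              f"between groups (max-T corrected)")
        for _, row in sig.iterrows():
            print(f"    {row.metric}: t={row.t:+.2f}, p_fwe={row.p_fwe:.4f}, "
                  f"d={row.cohens_d:+.2f}")
        prob_cols = [c for c in metrics.columns if c.startswith("probability_")]
        prof = metrics.groupby("group")[prob_cols].mean().T
        prof.index = [c.replace("probability_", "") for c in prof.index]
        out = ROOT / "results" / f"state_probability_profile_{task}.tsv"
        prof.to_csv(out, sep="\t")
        print(f"    group-mean state probabilities written to {out.name}")


if __name__ == "__main__":
    main()
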