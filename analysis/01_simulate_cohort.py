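"""Simulate the study cohort.

Generates a two-group cohort (22 group-A "control-like" vs 25 group-B
"case-like" subjects; 214 regions; MID and cue-reactivity tasks) with
planted effects that mirror a case-control reward study:

* group A carries stronger somatomotor-visual coupling (gain 3);
* group B carries stronger VMN-default-mode coupling (gain 3);
* during reward-anticipation windows, group B's VMN-DMN coupling is
  further raised (gain 6); during drug-cue blocks, group B's
  VMN-control coupling is raised (gain 6).

The gains are sized so the planted edges carry per-edge effects around
d ~ 1.5-2, the scale a familywise-corrected edge test can detect at
n = 22 vs 25.

The raw per-subject timeseries are large, so they are written under
scratch/cohort (regenerate by re-running this script); downstream scripts
read them from there and write only small summary tables under results/.

Usage: python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from taskfc.cohort import CohortSpec, ConditionEffect, CouplingEffect, generate_cohort
from taskfc.io import write_cohort

COHORT_DIR = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def study_spec(seed: int) -> CohortSpec:
    return CohortSpec(
        seed=seed,
        n_group_a=22,
        n_group_b=25,
        n_regions=214,
        coupling_effects=(
            CouplingEffect(("somatomotor", "visual"), "A", 3.0),
            CouplingEffect(("vmn", "default_mode"), "B", 3.0),
        ),
        condition_effects=(
            ConditionEffect(("vmn", "default_mode"), "reward_anticipation", "B", 6.0),
            ConditionEffect(("vmn", "control"), "drug", "B", 6.0),
        ),
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    spec = study_spec(args.seed)
    cohort = generate_cohort(spec)
    write_cohort(cohort, COHORT_DIR)
    n_vol = {t: cohort.subjects[0]["data"][t].timeseries.n_volumes
             for t in spec.tasks}
    print(f"wrote {spec.n_subjects} subjects x {len(spec.tasks)} tasks "
          f"({spec.n_regions} regions, volumes per task {n_vol}) to {COHORT_DIR}")
    print("planted: A somatomotor-visual x3; B vmn-dmn x3; "
          "B vmn-dmn x6 in reward anticipation; B vmn-control x6 in drug blocks")


if __name__ == "__main__":
    main()
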