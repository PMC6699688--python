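"""Generate the synthetic inputs for the downstream analysis steps: a
balanced 20 x 6 x 3 line x tester field trial (with 4 checks) and a
26-individual x 87-locus structured SSR panel, written in the CSV
dialects the I/O layer reads. Ground-truth effects go to JSON side-files.
"""

import json
from pathlib import Path

import numpy as np

from linetester.simulate import MarkerSimConfig, TrialSimConfig, simulate_markers, simulate_trial
from linetester.study_io import check_balance, write_genotypes, write_phenotypes

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 2019


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    trial_cfg = TrialSimConfig(check_count=4, seed=SEED)
    design, records, truth = simulate_trial(trial_cfg)
    problems = check_balance(records, design)
    assert not problems, problems
    write_phenotypes(OUT / "phenotypes.csv", records, ["y"])
    json.dump(
        {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()},
        open(OUT / "trial_truth.json", "w"), indent=2)
    print(f"trial: l={design.l}, t={design.t}, r={design.r}, "
          f"{len(records)} plot records -> {OUT/'phenotypes.csv'}")

    marker_cfg = MarkerSimConfig(seed=SEED)
    gm, mtruth = simulate_markers(marker_cfg)
    write_genotypes(OUT / "genotypes.csv", gm)
    json.dump({"subpop": mtruth["subpop"].tolist(), "dh_flags": mtruth["dh_flags"]},
              open(OUT / "marker_truth.json", "w"), indent=2)
    print(f"markers: {gm.shape[0]} individuals x {gm.shape[1]} loci "
          f"in {marker_cfg.n_subpops} subpopulations -> {OUT/'genotypes.csv'}")


if __name__ == "__main__":
    main()
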