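"""Line x tester ANOVA and combining ability on the simulated trial:
reads the plot-level phenotypes from step 01, fits the RCBD source
decomposition, and estimates GCA/SCA effects with standard errors,
critical differences and significance stars.
"""

from pathlib import Path

import pandas as pd

from linetester.anova import lt_anova
from linetester.combining import estimate_gca_sca, gca_sca_significance
from linetester.study_io import entry_means, read_phenotypes

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    design, records, = read_phenotypes(ROOT / "synthetic" / "phenotypes.csv", ["y"])
    anova = lt_anova(records, design, "y")
    anova.to_frame().to_csv(ROOT / "anova.tsv", sep="\t")
    print(anova.to_frame().round(3).to_string())

    cross_means = entry_means([r for r in records if r.role == "cross"], "y")
    ca = gca_sca_significance(
        estimate_gca_sca(cross_means, design), anova.error_ms, design,
        df_error=anova.error_df)
    gca = pd.DataFrame({
        "parent": ca.line_ids + ca.tester_ids,
        "role": ["line"] * design.l + ["tester"] * design.t,
        "gca": list(ca.gca_lines) + list(ca.gca_testers),
        "sig": ca.sig_gca_lines + ca.sig_gca_testers,
    })
    gca.to_csv(ROOT / "gca_effects.tsv", sep="\t", index=False)
    sca = pd.DataFrame(ca.sca, index=ca.line_ids, columns=ca.tester_ids)
    sca.to_csv(ROOT / "sca_effects.tsv", sep="\t")

    n_sig_lines = sum(1 for s in ca.sig_gca_lines if s)
    print(f"\n{n_sig_lines}/{design.l} lines have GCA significant at 5% "
          f"(CD95 line {ca.cd95_gca_line:.3f}, tester {ca.cd95_gca_tester:.3f}); "
          f"line x tester interaction F = {anova['Line x Tester Eff.'].F:.2f} "
          f"({anova['Line x Tester Eff.'].sig or 'ns'})")


if __name__ == "__main__":
    main()
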