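"""Trans-ethnic Bayes-factor screen and the carry-forward rule.

Computes the exact-enumeration trans-ethnic log10 Bayes factor for each
of the 27 published trait rows (effect prior SD = 0.2 x the
inverse-variance-weighted trait scale, since the published analysis
does not state its prior), then applies the selection rule of the
original screen: a trait is carried forward to mediation when its
fixed-effects meta p-value reaches the Bonferroni threshold 0.05/27 OR
its published log10 BF exceeds 1.5.

Note the BFs computed here use our own prior and therefore differ
numerically from the published column; the published BFs are used for
the selection rule, our BFs are reported alongside for comparison.
On the published numbers the rule selects Lp-PLA2 activity
(p = 0.001 <= 0.0019, BF 1.69) and the DPA/EPA ratio (BF 1.52 > 1.5) —
not the DHA/EPA ratio (p = 0.008, BF 1.09) that the original report's
narrative carried forward; the discrepancy is internal to that report
and is surfaced here rather than resolved.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from transmeta import fixed_effects_meta, transethnic_bf
from transmeta.pipeline import BF_THRESHOLD, bonferroni_threshold
from transmeta.published import MESA_RS10846744, study_estimates

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    threshold = bonferroni_threshold(0.05, 27)
    rows = []
    for trait, rec in MESA_RS10846744.items():
        ests = study_estimates(trait)
        mr = fixed_effects_meta(ests)
        # prior scale proportional to the combined-estimate scale
        sigma = 5.0 * mr.se
        bf = transethnic_bf(ests, sigma=sigma)
        pub = rec["meta"]
        carried = pub["p"] <= threshold or pub["log10_bf"] > BF_THRESHOLD
        rows.append(dict(
            trait=trait, meta_p=pub["p"], published_log10_bf=pub["log10_bf"],
            own_log10_bf=bf.log10_bf, sigma=sigma, carried=carried,
            top_partition="|".join(",".join(c) for c in bf.top_partitions(1)[0][0]),
        ))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "transethnic_screen.tsv", sep="\t", index=False)

    carried = df.loc[df.carried, "trait"].tolist()
    print(f"Bonferroni threshold 0.05/27 = {threshold:.6f}")
    print(f"carried forward: {carried}")
    print("note: the original narrative names DHA/EPA, but the stated rule "
          "selects DPA/EPA (published BF 1.52 > 1.5 vs DHA/EPA BF 1.09, "
          "p 0.008 > 0.0019); following the rule.")
    corr = np.corrcoef(df.published_log10_bf, df.own_log10_bf)[0, 1]
    print(f"rank agreement of own vs published BFs across 27 traits: r = {corr:.2f} "
          "(priors differ, so only the ordering is comparable)")


if __name__ == "__main__":
    main()
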