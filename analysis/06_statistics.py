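"""Statistical layer: per-harvest ANOVA with Duncan letters, correlations.

At every harvest date the plot means of total dry mass and leaf area are
compared across treatments by one-way ANOVA; where p < 0.05 Duncan's
multiple range test assigns letter groups.  Pearson correlation matrices
relate the interval growth indices within each treatment.  Writes
anova.csv, duncan_letters.csv and correlations.csv per trial; prints how
many harvests separate the treatments and the RGR-NAR correlation.
"""

import numpy as np
import pandas as pd
from _common import DESIGNS, outdir

from chiagrow import correlation_matrix, duncan_mrt, one_way_anova


def main() -> None:
    for trial, make_design in DESIGNS.items():
        design = make_design()
        out = outdir(trial)
        plants = pd.read_csv(out / "plants.csv")
        plants["dm_total_g"] = plants[
            ["dm_leaf_g", "dm_stem_g", "dm_root_g", "dm_inflo_g"]
        ].sum(axis=1)
        anova_rows, letter_rows = [], []
        for response in ("dm_total_g", "leaf_area_cm2"):
            n_sig = 0
            for das, grp in plants.groupby("das"):
                plot_means = grp.groupby(["treatment", "block"])[response].mean()
                groups = {
                    t: plot_means.loc[t].to_numpy()
                    for t in plot_means.index.get_level_values(0).unique()
                }
                table = one_way_anova(list(groups.values()))
                anova_rows.append(
                    {"response": response, "das": das, "F": table.f, "p": table.p}
                )
                if np.isfinite(table.f) and table.p < 0.05:
                    n_sig += 1
                    dr = duncan_mrt(groups, alpha=0.05)
                    for lab, mean, letters in zip(dr.labels, dr.means, dr.letters):
                        letter_rows.append(
                            {"response": response, "das": das, "treatment": lab,
                             "mean": mean, "letters": letters}
                        )
            total = plants["das"].nunique()
            print(f"{trial} {response}: treatments separated at {n_sig}/{total} harvests")
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
        if letter_rows:
            pd.DataFrame(letter_rows).to_csv(out / "duncan_letters.csv", index=False)

        indices = pd.read_csv(out / "indices_interval.csv")
        corr_frames = []
        for trt in design.treatments:
            iv = indices[indices["treatment"] == trt.label]
            r, p = correlation_matrix(iv[["rgr", "nar", "lar", "slw", "cgr"]])
            print(
                f"{trial} {trt.label}: r(RGR, NAR) = {r.loc['rgr', 'nar']:+.3f} "
                f"(p = {p.loc['rgr', 'nar']:.3g})"
            )
            r = r.round(4).assign(treatment=trt.label, index=r.index)
            corr_frames.append(r)
        pd.concat(corr_frames, ignore_index=True).to_csv(
            out / "correlations.csv", index=False
        )


if __name__ == "__main__":
    main()
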