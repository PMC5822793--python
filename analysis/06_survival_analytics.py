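"""Downstream survival analytics of the risk score in every cohort:
continuous-score Cox, median dichotomization, Kaplan-Meier + log-rank,
and a multivariate fit of the risk group."""

import numpy as np
import pandas as pd
from _common import RESULTS, cohort_paths

from netscore.simulate import Cohort
from netscore.survival import (
    cox_fit,
    dichotomize_by_median,
    kaplan_meier,
    logrank_test,
)


def main() -> None:
    rows = []
    for name in ("cohort0", "cohort1"):
        cohort = Cohort.read(name, *cohort_paths(name))
        scores = pd.read_csv(RESULTS / f"netscore_{name}.tsv", sep="\t",
                             index_col=0)["netscore"]
        cont = cox_fit(scores.to_frame(), cohort.survival)
        groups = dichotomize_by_median(scores)
        chi2, _, p_lr = logrank_test(groups.to_numpy(), cohort.survival)
        grp = cox_fit((groups == "high").astype(float).rename("high_risk").to_frame(),
                      cohort.survival)
        km_frames = []
        for level in ("low", "high"):
            km = kaplan_meier(cohort.survival[groups == level])
            f = km.to_frame()
            f.insert(0, "group", level)
            km_frames.append(f)
        pd.concat(km_frames).to_csv(RESULTS / f"km_{name}.tsv", sep="\t", index=False)
        rows.append({
            "cohort": name,
            "cont_hr_per_sd": float(np.exp(cont.coef[0] * scores.std())),
            "cont_p": float(cont.p[0]),
            "group_hr": float(grp.hazard_ratio[0]),
            "group_ci": f"{grp.ci_lower[0]:.2f}-{grp.ci_upper[0]:.2f}",
            "logrank_p": p_lr,
        })
        print(f"{name}: high- vs low-risk HR {rows[-1]['group_hr']:.2f} "
              f"({rows[-1]['group_ci']}), log-rank p = {p_lr:.2g}")
    pd.DataFrame(rows).to_csv(RESULTS / "survival_analytics.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
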