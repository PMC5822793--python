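"""Screen module eigengenes against overall survival in the training
cohort and validate the hits in the independent test cohort; modules
significant everywhere (uncorrected p < 0.05) advance."""

import json

import pandas as pd
from _common import RESULTS, cohort_paths

from netscore.modules import screen_modules, surviving_modules, validate_modules
from netscore.network import module_eigengenes
from netscore.simulate import Cohort
from netscore.treecut import ModuleAssignment


def frame(results):
    return pd.DataFrame(
        [{"module": r.module, "hr": r.hazard_ratio, "p": r.p,
          "significant": r.significant} for r in results]
    )


def main() -> None:
    training = Cohort.read("cohort0", *cohort_paths("cohort0"))
    test = Cohort.read("cohort1", *cohort_paths("cohort1"))
    labels = pd.read_csv(RESULTS / "module_assignment.tsv", sep="\t",
                         index_col=0)["module"]
    assignment = ModuleAssignment(labels, 0.99, 2, 30)

    mes = module_eigengenes(training.expression, assignment)
    screen = screen_modules(mes, training.survival)
    frame(screen).to_csv(RESULTS / "screen_training.tsv", sep="\t", index=False)
    sig = [r.module for r in screen if r.significant]
    print(f"training screen: {sig} significant of {len(screen)} modules")

    val = validate_modules(assignment, test)
    frame(val).to_csv(RESULTS / "screen_test.tsv", sep="\t", index=False)
    print(f"test-cohort validation: {[r.module for r in val if r.significant]}")

    advanced = surviving_modules(screen, [val])
    (RESULTS / "advanced_modules.json").write_text(
        json.dumps({"modules": advanced}, indent=1) + "\n"
    )
    print(f"advancing to model building: {advanced}")


if __name__ == "__main__":
    main()
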