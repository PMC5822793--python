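"""Cross-validate and train the convolutional Cox scoring network on the
selected genes, score both cohorts, and compare against a conventional
multivariate Cox model on the same gene panel."""

import pandas as pd
from _common import RESULTS, SCRATCH, SEED, cohort_paths

from netscore.model import (
    TrainingConfig,
    compare_with_cox_baseline,
    fit_cv_model,
    predict_netscore,
)
from netscore.simulate import Cohort
from netscore.survival import concordance_index

GRID = [
    ({"filters_per_module": f, "fc_layer_sizes": fc},
     TrainingConfig(learning_rate=1e-2, epochs=ep))
    for f in (4, 8)
    for fc in ((32, 16, 8), (16, 8, 4))
    for ep in (150, 300)
]


def main() -> None:
    training = Cohort.read("cohort0", *cohort_paths("cohort0"))
    test = Cohort.read("cohort1", *cohort_paths("cohort1"))
    sel = pd.read_csv(RESULTS / "selected_genes.tsv", sep="\t")
    blocks = tuple(
        (mod, tuple(sub.sort_values("rank")["gene"]))
        for mod, sub in sel.groupby("module", sort=False)
    )

    model = fit_cv_model(training, blocks, grid=GRID, k=5, seed=SEED)
    model.cv_record.table.to_csv(RESULTS / "cv_table.tsv", sep="\t", index=False)
    chosen = model.cv_record.chosen
    print(f"5-fold CV chose filters={chosen['filters_per_module']}, "
          f"fc={chosen['fc_layer_sizes']}, epochs={chosen['epochs']} "
          f"(mean fold C = {chosen['mean_c']:.3f})")
    model.save(SCRATCH / "model")

    for cohort in (training, test):
        scores = predict_netscore(model, cohort)
        scores.to_frame().to_csv(RESULTS / f"netscore_{cohort.name}.tsv", sep="\t",
                                 index_label="sample")
        c = concordance_index(scores, cohort.survival, seed=SEED)
        print(f"{cohort.name}: C-index {c.c_index:.3f} +/- {c.se:.3f}")

    genes = sel["gene"].tolist()
    comparison = compare_with_cox_baseline(
        [training, test], genes, blocks, seed=SEED,
        training_config=TrainingConfig(epochs=300, seed=SEED),
    )
    comparison.to_csv(RESULTS / "cox_comparison.tsv", sep="\t", index=False)
    held = comparison[comparison["cohort"] == "cohort1"].iloc[0]
    print(f"test cohort: network C {held['netscore_c']:.3f} vs "
          f"linear Cox C {held['cox_c']:.3f} on the same {len(genes)} genes")


if __name__ == "__main__":
    main()
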