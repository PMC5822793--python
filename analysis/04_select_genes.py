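"""Select the representative genes of the validated modules: rank module
members by |kME| (gene module membership) and keep the top 10 of each,
after confirming kME tracks univariate survival significance."""

import json

import pandas as pd
from _common import RESULTS, cohort_paths

from netscore.modules import (
    gene_significance,
    gmm_significance_correlation,
    select_representative_genes,
)
from netscore.network import gene_module_membership, module_eigengenes
from netscore.simulate import Cohort
from netscore.treecut import ModuleAssignment


def main() -> None:
    training = Cohort.read("cohort0", *cohort_paths("cohort0"))
    labels = pd.read_csv(RESULTS / "module_assignment.tsv", sep="\t",
                         index_col=0)["module"]
    assignment = ModuleAssignment(labels, 0.99, 2, 30)
    advanced = json.loads((RESULTS / "advanced_modules.json").read_text())["modules"]

    mes = module_eigengenes(training.expression, assignment)
    gmm = gene_module_membership(training.expression, mes)

    rows = []
    for mod in advanced:
        members = assignment.module_genes(mod)
        sig = gene_significance(training.expression.loc[members], training.survival)
        r, p = gmm_significance_correlation(gmm.loc[members], sig, mod)
        print(f"{mod}: |kME| vs -log10(p) correlation r = {r:.2f} (p = {p:.2g})")
        for rank, gene in enumerate(
            select_representative_genes(gmm, members, k=10, module=mod), start=1
        ):
            rows.append({"module": mod, "rank": rank, "gene": gene,
                         "kME": gmm.loc[gene, mod]})
    sel = pd.DataFrame(rows)
    sel.to_csv(RESULTS / "selected_genes.tsv", sep="\t", index=False)
    print(f"selected {len(sel)} genes "
          f"({', '.join(f'{m}: 10' for m in advanced)}) as model input")


if __name__ == "__main__":
    main()
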