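#!/usr/bin/env python
"""Phenotype overlap and category enrichment of the biofilm-deficient set.

Reproduces the overlap arithmetic on the published phenotype chain (71
biofilm-deficient genes, 69 of them mat-deficient, 49 of those also
invasion-deficient): the three-way Venn partition, the 69% invasive
overlap, and the chance expectation for the cross-study comparison with
an external 655-gene mat screen in the same 4019-gene library. Finishes
with a category-enrichment example on a synthetic annotation.
"""

import json
from pathlib import Path

import numpy as np

from biofilmscreen.io import write_table
from biofilmscreen.setstats import GeneSet, enrich_categories, overlap, venn3

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main(seed: int = 1):
    genes = [f"g{i}" for i in range(71)]
    biofilm = GeneSet("biofilm_deficient", genes)
    mat = GeneSet("mat_deficient", genes[:69])
    invasive = GeneSet("invasion_deficient", genes[:49])

    regions = venn3(biofilm, mat, invasive)
    inv = overlap(biofilm, invasive, universe_size=4019)
    print(
        f"{len(biofilm)} biofilm-deficient genes: {len(mat)} also mat-deficient, "
        f"{regions['abc']} lost all three phenotypes "
        f"({round(inv.percent_of_a)}% of the biofilm set is invasion-deficient)"
    )

    chance = overlap(
        GeneSet("biofilm_mat", genes[:69]),
        GeneSet("mat_external", [f"m{i}" for i in range(655)]),
        universe_size=4019,
    )
    print(
        f"cross-study: chance expectation for 69 vs 655 genes in a 4019-gene "
        f"library is {chance.expected_overlap:.2f} genes (identity expectation: 69)"
    )

    # enrichment demo: one planted category concentrated in the hit set
    rng = np.random.default_rng(seed)
    universe = GeneSet("universe", [f"g{i}" for i in range(4019)])
    annotation = {f"g{i}": ["planted_pathway"] for i in range(40)}
    for i in rng.choice(np.arange(71, 4019), size=300, replace=False):
        annotation.setdefault(f"g{i}", []).append(f"background_{i % 5}")
    enr = enrich_categories(biofilm, annotation, universe)
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(enr, OUT / "enrichment.tsv")
    top = enr.iloc[0]
    print(
        f"top enriched category: {top['category']} "
        f"(k={top['k']}/{top['K']}, adjusted p = {top['p_adjusted']:.3g})"
    )
    (OUT / "phenotype_overlap.json").write_text(
        json.dumps(
            {
                "venn": {k: v for k, v in regions.items() if k != "labels"},
                "percent_invasive_of_biofilm": round(inv.percent_of_a),
                "chance_expected_cross_study_overlap": round(chance.expected_overlap, 2),
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main()
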