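#!/usr/bin/env python
"""Validate the clock on the held-out test set.

Scores proteomic age, then: Spearman correlation with chronological age;
Cox mortality and Fine-Gray incident-disease associations of age deviation
across the three adjustment tiers with BH-FDR; Harrell's C comparison of
proteomic age versus chronological age.  Writes scores and all tables.
"""

from pathlib import Path

import pandas as pd

from protclock import (PACModel, compare_models_c, correlation_panel,
                       default_tiers, run_association_suite, score_cohort)
from protclock.io import read_cohort, read_protein_matrix

OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.tsv")
    matrix = read_protein_matrix(OUT / "matrix_imputed.tsv")
    pac = PACModel.load(OUT / "model.yaml")
    test_ids = pd.read_csv(OUT / "test_ids.tsv", sep="\t")["participant_id"]

    test = cohort.loc[test_ids]
    scores = score_cohort(pac, matrix, test)
    scores.to_csv(OUT / "scores.tsv", sep="\t")
    data = test.join(scores)
    print(f"test set: mean proteomic age {scores['proteomic_age'].mean():.1f} y "
          f"(chronological {test['age'].mean():.1f} y), "
          f"deviation SD {scores['deviation'].std():.2f} y")

    corr = correlation_panel(data, ["age", "proteomic_age"], "spearman")
    corr.to_csv(OUT / "correlations.tsv", sep="\t")
    print(f"Spearman r(proteomic age, chronological age) = "
          f"{corr.loc['age', 'proteomic_age']:.3f}")

    outcomes = ["mortality", "heart_failure", "diabetes"]
    assoc = run_association_suite(data, "deviation", outcomes, default_tiers())
    assoc.to_csv(OUT / "associations.tsv", sep="\t", index=False)
    mort = assoc.query("outcome == 'mortality' and tier == 'age_adjusted'").iloc[0]
    print(f"mortality HR per year of deviation (age-adjusted): "
          f"{mort['hr']:.3f} [{mort['ci_low']:.3f}, {mort['ci_high']:.3f}]")
    n_sig = int((assoc["p_adj"] < 0.05).sum())
    print(f"{n_sig}/{len(assoc)} associations FDR-significant across "
          f"{assoc['tier'].nunique()} tiers")

    comp = compare_models_c(data, ["age", "proteomic_age"], "time_death", "died")
    comp.to_csv(OUT / "concordance.tsv", sep="\t")
    print("Harrell's C (mortality): "
          + ", ".join(f"{s}={comp.loc[s, 'c']:.3f}" for s in comp.index))
    print(f"wrote {OUT}/scores.tsv, associations.tsv, concordance.tsv")


if __name__ == "__main__":
    main()
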