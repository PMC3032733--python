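#!/usr/bin/env python
"""Bivariate and trivariate Cholesky decompositions of the "added value" design.

For each covariate -> outcome ordering, reports the independent (final-factor)
A/C/E contributions to the outcome and their re-standardization to the
covariate-free variance, and compares the re-standardized heritability with
the univariate fit of the corresponding regression-residualized trait.
Writes results/cholesky.csv.
"""

from pathlib import Path

import pandas as pd

from twinace import fit_ace, fit_cholesky, genetic_correlation, read_cohort
from twinace.pipeline import reference_study

OUT = Path(__file__).resolve().parents[1] / "results"

RESIDUAL_TWIN = {
    ("g", "ach12_teacher"): "gfree_teacher",
    ("g", "ach12_test"): "gfree_test",
    ("ach10_teacher", "ach12_teacher"): "prevfree_teacher",
    ("ach10_test", "ach12_test"): "prevfree_test",
    ("ach10_teacher", "g", "ach12_teacher"): "bothfree_teacher",
    ("ach10_test", "g", "ach12_test"): "bothfree_test",
}


def main() -> None:
    cfg = reference_study()
    data = read_cohort(OUT / "cohort_corrected.csv")

    rows = []
    for order in (*cfg.bivariate, *cfg.trivariate):
        fit = fit_cholesky(data, order)
        ind, restd = fit.independent, fit.restandardized
        resid_trait = RESIDUAL_TWIN[tuple(order)]
        uni = fit_ace(data, resid_trait, ci=False)
        rg = genetic_correlation(fit, order[0], order[-1])
        rows.append({
            "model": " -> ".join(order),
            "independent_A": ind[0], "independent_C": ind[1], "independent_E": ind[2],
            "restd_A": restd[0], "restd_C": restd[1], "restd_E": restd[2],
            "residual_route_A": uni.A, "residual_route_C": uni.C, "residual_route_E": uni.E,
            "genetic_correlation": rg,
        })
        print(f"{' -> '.join(order)}")
        print(f"  independent A/C/E: {ind[0]:.2f}/{ind[1]:.2f}/{ind[2]:.2f} "
              f"(sum {sum(ind):.2f})")
        print(f"  re-standardized:   {restd[0]:.2f}/{restd[1]:.2f}/{restd[2]:.2f}")
        print(f"  residual route ({resid_trait}): {uni.A:.2f}/{uni.C:.2f}/{uni.E:.2f}")
        print(f"  genetic correlation r_g({order[0]}, {order[-1]}) = {rg:.2f}\n")

    pd.DataFrame(rows).to_csv(OUT / "cholesky.csv", index=False)
    print(f"wrote {OUT / 'cholesky.csv'}")


if __name__ == "__main__":
    main()
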