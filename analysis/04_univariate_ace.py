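#!/usr/bin/env python
"""Univariate FIML ACE decompositions with profile-likelihood 95% CIs.

Fits the raw, g-free, previous-achievement-free and doubly-corrected
achievement traits plus g; writes results/univariate_ace.csv.  Components
whose CI lower bound sits at 0 are flagged NS.
"""

from pathlib import Path

import pandas as pd

from twinace import fit_ace, read_cohort
from twinace.pipeline import reference_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = reference_study()
    data = read_cohort(OUT / "cohort_corrected.csv")

    rows = []
    for t in cfg.univariate_traits:
        fit = fit_ace(data, t, ci=True)
        row = {"trait": t, "n_MZ": fit.n_pairs_mz, "n_DZ": fit.n_pairs_dz,
               "loglik": fit.loglik}
        for comp in ("A", "C", "E"):
            lo, hi = getattr(fit, f"ci_{comp}")
            row[comp] = getattr(fit, comp)
            row[f"{comp}_lo"], row[f"{comp}_hi"] = lo, hi
            row[f"{comp}_NS"] = fit.ns_flags[comp]
        rows.append(row)
        print(f"{t:<20} " + "  ".join(
            f"{c}={row[c]:.2f} ({row[f'{c}_lo']:.2f}-{row[f'{c}_hi']:.2f})"
            + (" NS" if row[f"{c}_NS"] else "")
            for c in ("A", "C", "E")))

    pd.DataFrame(rows).to_csv(OUT / "univariate_ace.csv", index=False)
    print(f"\nwrote {OUT / 'univariate_ace.csv'}")


if __name__ == "__main__":
    main()
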