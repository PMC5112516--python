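#!/usr/bin/env python
"""Fit every simulated titration and assemble a study-table-style report.

Reads the CSVs written by 01_simulate_titrations.py, fits each with the
nested bisection + least-squares procedure, and writes
results/fitted_titrations.tsv (K_D at integer uM, n at one decimal, the
table's precision) plus per-protein full-precision JSON.
"""

import json
from pathlib import Path

from sul7d.cli_io import read_titration_csv
from sul7d.titration_fit import fit_titration

ROOT = Path(__file__).resolve().parent.parent
IN = ROOT / "results" / "titrations"
OUT = ROOT / "results"


def main() -> None:
    rows = ["name\tkd_uM\tn_bases\tq_max\tconverged"]
    full = {}
    for path in sorted(IN.glob("*.csv")):
        exp = read_titration_csv(path)
        fit = fit_titration(exp)
        rows.append(
            f"{path.stem}\t{fit.kd_uM:.0f} ± {fit.se['kd_uM']:.0f}\t"
            f"{fit.params.n:.1f} ± {fit.se['n']:.1f}\t"
            f"{fit.params.q_max:.2f}\t{fit.converged}"
        )
        full[path.stem] = fit.to_dict()
    (OUT / "fitted_titrations.tsv").write_text("\n".join(rows) + "\n")
    (OUT / "fitted_titrations.json").write_text(json.dumps(full, indent=2) + "\n")
    print("\n".join(rows))
    print(f"\nwrote {len(full)} fits to {OUT}/fitted_titrations.{{tsv,json}}")


if __name__ == "__main__":
    main()
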