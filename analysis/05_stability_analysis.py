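#!/usr/bin/env python
"""Thermostability analytics: group statistics, key deltas, determinant rule.

Reproduces the stability arithmetic on the packaged table: the high/low Tm
group means and sample SDs, the I17T penalty (Sis7b - Sis7a) and the
Sto7 - Aho7c increment, and the position-17/30 determinant consistency
check.  Writes results/stability_report.json.
"""

import json
from pathlib import Path

from sul7d.datasets import load_stability_records, load_study_sequences
from sul7d.stability_analysis import (
    delta_tm,
    determinant_check,
    split_by_tm_gap,
    tm_group_stats,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = load_stability_records()
    out = {}
    for group in ("high", "low"):
        stats = tm_group_stats(records, group)
        out[f"{group}_tm_group"] = {
            "mean_c": round(stats.mean, 1),
            "sd_c": round(stats.sd, 1),
            "n": stats.n,
            "members": list(stats.members),
        }
    out["delta_tm_sis7b_minus_sis7a_c"] = round(delta_tm(records, "Sis7b", "Sis7a"), 1)
    out["delta_tm_sto7_minus_aho7c_c"] = round(delta_tm(records, "Sto7", "Aho7c"), 1)
    out["largest_gap_split_matches_groups"] = (
        set(split_by_tm_gap(records)["high"])
        == {r.name for r in records if r.group == "high"}
    )
    report = determinant_check(records, load_study_sequences())
    out["determinant_check"] = {
        "rows": [dict(r) for r in report.rows],
        "consistent": report.n_consistent,
        "violations": report.n_violations,
        "excluded_aggregating": list(report.excluded),
    }
    (OUT / "stability_report.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
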