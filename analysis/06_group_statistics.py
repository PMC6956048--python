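"""Group-comparison statistics for every quantified endpoint.

One-way ANOVA across the five groups plus pairwise Student t tests against
the control and the ectatic model group, for Young's modulus, denaturation
temperature and per-gene log2 fold change.
Writes results/tables/group_statistics.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from corneaquant.expression import one_way_anova, two_sample_t

ROOT = Path(__file__).resolve().parents[1]
TABLES = ROOT / "results" / "tables"


def endpoint_frames():
    ym = pd.read_csv(TABLES / "young_modulus.csv")
    yield "young_modulus_MPa", {
        g: s["young_modulus_MPa"].to_numpy() for g, s in ym.groupby("group")
    }
    td = pd.read_csv(TABLES / "denaturation.csv")
    yield "td_C", {g: s["td_C"].to_numpy() for g, s in td.groupby("group")}


def main() -> None:
    rows = []
    for endpoint, by_group in endpoint_frames():
        res = one_way_anova(list(by_group.values()))
        rows.append(
            {
                "endpoint": endpoint,
                "comparison": "anova_all_groups",
                "statistic": round(res.statistic, 4),
                "p": res.p_two_sided,
            }
        )
        for ref in ("control", "KC"):
            for grp, vals in by_group.items():
                if grp == ref:
                    continue
                t = two_sample_t(vals, by_group[ref], variant="student")
                rows.append(
                    {
                        "endpoint": endpoint,
                        "comparison": f"{grp}_vs_{ref}",
                        "statistic": round(t.statistic, 4),
                        "p": t.p_two_sided,
                    }
                )
    table = pd.DataFrame(rows)
    table["significant_0.05"] = table["p"] < 0.05
    table.to_csv(TABLES / "group_statistics.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    n_sig = int(table["significant_0.05"].sum())
    print(f"\n{n_sig}/{len(table)} comparisons significant at alpha = 0.05.")


if __name__ == "__main__":
    main()
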