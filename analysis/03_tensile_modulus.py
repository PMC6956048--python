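"""Young's modulus per treatment group from the simulated strip tests.

Reads the tensile CSVs written by 01_simulate_inputs.py, reduces each to an
engineering stress-strain curve, and fits the tangent-window modulus
(70-90% of max strain). Writes results/tables/young_modulus.csv.
"""

from pathlib import Path

import pandas as pd

from corneaquant.config import validate_config
from corneaquant.io import read_tensile_csv
from corneaquant.mechanics import compute_stress_strain, estimate_modulus

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data" / "tensile"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    cfg = validate_config(None)
    sec = cfg.section("tensile")
    rows = []
    for group in cfg.groups:
        for path in sorted(DATA.glob(f"{group}_*.csv")):
            curve = compute_stress_strain(read_tensile_csv(path))
            est = estimate_modulus(curve, sec["fit_lo_frac"], sec["fit_hi_frac"])
            rows.append(
                {
                    "group": group,
                    "replicate": path.stem,
                    "young_modulus_MPa": round(est.young_modulus_MPa, 4),
                    "r_squared": round(est.r_squared, 5),
                }
            )
    table = pd.DataFrame(rows)
    TABLES.mkdir(parents=True, exist_ok=True)
    table.to_csv(TABLES / "young_modulus.csv", index=False)
    means = table.groupby("group", sort=False)["young_modulus_MPa"].agg(["mean", "std"])
    print(means.round(3).to_string())
    e = means["mean"]
    print(
        f"\nenzyme weakening dropped E to {e['KC']:.2f} MPa "
        f"(control {e['control']:.2f}); cornea-particle treatment restored it to "
        f"{e['COR']:.2f} MPa (+{(e['COR'] - e['KC']) / e['KC'] * 100:.0f}% over KC)."
    )


if __name__ == "__main__":
    main()
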