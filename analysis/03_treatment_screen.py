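#!/usr/bin/env python
"""Treatment screen: emapunil attenuation and control contrasts.

Reads results/metrics.csv and writes per-compartment comparisons:

* results/screen_lps_vs_emapunil.{json,csv,md} — does emapunil pretreatment
  attenuate the LPS-evoked ΔΨm rise, and where (soma / branches / endfeet)?
* results/screen_baseline_vs_emapunil.{json,csv,md} — does emapunil alone
  move baseline ΔΨm? (expected: no)

Also prints the whole-cell microglia-vs-neuron contrast under LPS.
"""

from pathlib import Path

import pandas as pd

from mitoscreen.stats import class_contrast, screen_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def write(rep, stem: str) -> None:
    rep.to_json(RESULTS / f"{stem}.json")
    rep.comparisons.to_csv(RESULTS / f"{stem}.csv", index=False, float_format="%.6g")
    (RESULTS / f"{stem}.md").write_text(rep.to_markdown())


def main() -> None:
    metrics = pd.read_csv(RESULTS / "metrics.csv")

    rep = screen_report(metrics, control="lps", treatment="lps_emapunil")
    write(rep, "screen_lps_vs_emapunil")
    tot = rep.comparisons.query(
        "metric == 'total_pct_change' and cell_class == 'microglia'"
    )
    print("LPS vs LPS+emapunil, total percent change per compartment:")
    print(tot[["compartment", "mean_control", "mean_treatment", "t", "p",
               "significant"]].to_string(index=False))

    null = screen_report(metrics, control="baseline", treatment="emapunil_only")
    write(null, "screen_baseline_vs_emapunil")
    n_sig = int(null.comparisons["significant"].sum())
    print(f"\nbaseline vs emapunil-only: {n_sig} significant comparisons "
          f"of {len(null.comparisons)} (expected ~5% false positives)")

    contrast = class_contrast(metrics, "lps")
    if contrast is not None:
        row = contrast.iloc[0]
        print(f"\nLPS whole-cell contrast: microglia {row.mean_treatment:.1f}% vs "
              f"neuron {row.mean_control:.1f}% (t={row.t:.2f}, p={row.p:.2g})")


if __name__ == "__main__":
    main()
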