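#!/usr/bin/env python
"""Stage 5 — 4PL potency fits and inhibition-mode analysis.

Simulates UDP-Glo-style dose-response data (0.25-500 uM doses, n = 3, 5% CV)
at the measured potencies — 21.8 uM (luminescence assay), 20.2 uM (HPLC) and
3.5 uM (reference inhibitor) — fits the 4PL, then reproduces the
inhibition-mode experiment: IC50 versus UDP-GlcNAc concentration over
2-400 uM for each candidate mechanism, compared with the Cheng-Prusoff
closed forms.
"""

from pathlib import Path

import pandas as pd

from ogtscreen.assay_models import (
    InhibitionModel,
    fit_4pl,
    ic50_vs_substrate,
    simulate_dose_response,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for label, planted in (("L01_udpglo", 21.8), ("L01_hplc", 20.2), ("reference", 3.5)):
    dr = simulate_dose_response(fourpl=(0.0, 1.0, planted, 1.0), replicates=3,
                                noise_cv=0.05, seed=2024)
    fit = fit_4pl(dr)
    rows.append({"assay": label, "planted_ic50_uM": planted,
                 "fitted_ic50_uM": round(fit.ic50, 2),
                 "hill": round(fit.hill, 2),
                 "se_ic50": round(fit.se.get("ic50", float("nan")), 2)})
potency = pd.DataFrame(rows)
potency.to_csv(OUT / "05_potency_fits.tsv", sep="\t", index=False)
print(potency.to_string(index=False))

mode_frames = []
for mode, alpha in (("competitive", 1.0), ("noncompetitive", 1.0),
                    ("uncompetitive", 1.0), ("mixed", 3.0)):
    df = ic50_vs_substrate(InhibitionModel(mode, ki=10.0, km=20.0, alpha=alpha),
                           noise_cv=0.05, replicates=3, seed=2024)
    df.insert(0, "mode", mode)
    mode_frames.append(df)
modes = pd.concat(mode_frames)
modes.to_csv(OUT / "05_ic50_vs_substrate.tsv", sep="\t", index=False,
             float_format="%.3f")
comp = modes[modes["mode"] == "competitive"]
print("\ncompetitive mode: fitted IC50 rises with substrate "
      f"({comp.fitted_ic50_uM.iloc[0]:.1f} -> {comp.fitted_ic50_uM.iloc[-1]:.1f} uM "
      "over 2 -> 400 uM UDP-GlcNAc), the signature seen for the screen hit above 25 uM")
nc = modes[modes["mode"] == "noncompetitive"]
print("noncompetitive mode: IC50 flat "
      f"({nc.fitted_ic50_uM.min():.1f}-{nc.fitted_ic50_uM.max():.1f} uM)")
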