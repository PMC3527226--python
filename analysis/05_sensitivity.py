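#!/usr/bin/env python
"""Time-dependent metabolic control coefficients of nuclear phospho-STAT1.

Computes the -1% finite-difference MCC of every kinetic parameter on STAT1Dn
for both cell-type presets, the CI band over 20 parameter sets along the
nuclear-dephosphorylation profile (from analysis/03), and 50% inhibition
simulations for the most sensitive parameters.  Writes
results/mcc_summary.csv and results/inhibition_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stat1ple import make_preset
from stat1ple.mcc import default_mcc_grid, inhibition_sim, mcc, mcc_band
from stat1ple.profiles import LikelihoodProfile, ThresholdSpec, ci_threshold

OUT = Path(__file__).resolve().parents[1] / "results"
grid = default_mcc_grid()
KINETIC = [
    "k_act", "k_inact", "R_tot", "k_phos", "k_inh", "k_impD", "k_impU",
    "k_exp", "k_deph", "k_tc_socs", "d_m_socs", "k_tl_socs", "d_socs",
    "b_m_stat", "k_tc_stat", "d_m_stat", "k_tl_stat", "d_stat",
    "tau_socs", "tau_stat",
]

rows = []
ranking = {}
for cell_type in ("PSC_like", "PC_like"):
    params = make_preset(cell_type)
    scores = {}
    for name in KINETIC:
        if params[name] <= 0:
            continue
        series = mcc(params, name, "STAT1Dn", time_grid=grid)
        scores[name] = float(np.nanmax(np.abs(series.coefficient)))
        for t, c in zip(grid, series.coefficient):
            rows.append((cell_type, name, t, float(c)))
    ranking[cell_type] = sorted(scores, key=scores.get, reverse=True)[:5]
    print(f"{cell_type}: most sensitive parameters for STAT1Dn:")
    for name in ranking[cell_type]:
        print(f"    {name:10s} max|C| = {scores[name]:.3f}")

pd.DataFrame(rows, columns=["cell_type", "parameter", "time_min", "coefficient"]).to_csv(
    OUT / "mcc_summary.csv", index=False, float_format="%.5g"
)

# CI band of the k_deph coefficient over PLE parameter sets (20, as in the
# reported sensitivity analysis), if analysis/03 produced the profile
band_summary = {}
prof_path = OUT / "profile_PSC_like_k_deph.json"
if prof_path.exists():
    prof = LikelihoodProfile.from_json(prof_path)
    threshold = ci_threshold(ThresholdSpec(0.95, 5))
    band = mcc_band(prof, "k_deph", "STAT1Dn", time_grid=grid,
                    threshold=threshold, n_sets=20)
    width = np.nanmax(band.band_upper - band.band_lower)
    band_summary["k_deph_band_max_width"] = float(width)
    print(f"PSC k_deph MCC band over 20 CI sets: max width {width:.3f}")

# 50% inhibition versus the local coefficients
inhibition = {}
for cell_type in ("PSC_like", "PC_like"):
    params = make_preset(cell_type)
    inhibition[cell_type] = {}
    for name in ("k_deph", "k_phos", "k_tc_socs"):
        out = inhibition_sim(params, name, 0.5, time_grid=grid)
        series = mcc(params, name, "STAT1Dn", time_grid=grid)
        inhibition[cell_type][name] = {
            "late_relative_change": float(out["relative_change"][-1]),
            "late_coefficient": float(series.coefficient[-1]),
            "signs_agree": bool(
                np.sign(out["relative_change"][-1]) == -np.sign(series.coefficient[-1])
            ),
        }
print("50% inhibition vs local coefficients (late time):")
for cell_type, block in inhibition.items():
    for name, rec in block.items():
        print(
            f"    {cell_type} {name}: change {rec['late_relative_change']:+.2%}, "
            f"C {rec['late_coefficient']:+.2f}, signs agree: {rec['signs_agree']}"
        )

(OUT / "inhibition_summary.json").write_text(
    json.dumps({"ranking": ranking, "band": band_summary, "inhibition": inhibition},
               indent=2)
)
print(f"wrote {OUT / 'mcc_summary.csv'} and {OUT / 'inhibition_summary.json'}")
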