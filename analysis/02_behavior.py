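#!/usr/bin/env python
"""Behavioral analysis of the simulated rating experiment.

Computes the dichotomized hit/false-alarm rates (ratings 4-6 = "present"),
decision criterion c and d' per participant; per-rating positive and negative
predictive values; the detection rate as a function of pre-stimulus baseline
pupil size (quintiles) with linear/quadratic contrasts; and the detection
rate over five chronological session parts.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gradedsdt.behavioral import (chronological_split_rates, predictive_values,
                                  pupil_quintile_rates,
                                  summaries_by_participant)
from gradedsdt.waveforms import polynomial_contrast_test

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    trials = pd.read_csv(OUT / "trials.csv")
    per = summaries_by_participant(trials, cut=3)
    per.to_csv(OUT / "behavior_summaries.csv", index=False)
    print(f"group means (N={len(per)}): "
          f"H={100 * per.hit_rate.mean():.1f}%, "
          f"FA={100 * per.fa_rate.mean():.1f}%, "
          f"c={per.criterion_c.mean():.2f} (SD {per.criterion_c.std():.2f}), "
          f"d'={per.d_prime.mean():.2f}")

    pv = predictive_values(trials)
    pv.to_csv(OUT / "predictive_values.csv", index=False)
    print("PPV by rating:", np.round(pv.PPV.to_numpy(), 2))
    print("NPV by rating:", np.round(pv.NPV.to_numpy(), 2))

    rates, table = pupil_quintile_rates(trials, cut=3)
    table.to_csv(OUT / "pupil_quintiles.csv", index=False)
    mat = table.pivot(index="participant_id", columns="bin",
                      values="rate").to_numpy()
    contrast = polynomial_contrast_test(mat)
    print(f"detection rate by baseline-pupil quintile: {np.round(rates, 3)}")
    print(f"  linear F={contrast.linear_f:.2f} (p={contrast.linear_p:.3g}), "
          f"quadratic F={contrast.quadratic_f:.2f} "
          f"(p={contrast.quadratic_p:.3g})")

    split, stable = chronological_split_rates(trials, n_parts=5, cut=3)
    stable.to_csv(OUT / "chronological_split.csv", index=False)
    print(f"detection rate by chronological fifth: {np.round(split, 3)}")

    (OUT / "behavior_group.json").write_text(json.dumps({
        "hit_rate": per.hit_rate.mean(), "fa_rate": per.fa_rate.mean(),
        "criterion_c": per.criterion_c.mean(), "d_prime": per.d_prime.mean(),
        "quintile_rates": rates.tolist(),
        "chronological_rates": split.tolist()}, indent=2) + "\n")


if __name__ == "__main__":
    main()
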