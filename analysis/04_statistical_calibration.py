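"""Calibration and power of the nonparametric statistics layer.

Two simulations: (1) type-I error — identical log-normal groups, 500
replicates, rejection rates of Mann-Whitney, Kruskal-Wallis and Conover
pairwise tests at alpha = 0.05 should sit near 5%; (2) power/construct
validity — two groups at the demo cohort's old-control vs patient-like
central values (FDsavg 16 vs 23, sFRR 7 vs 11, IQR-matched log-normal
spreads, n = 10 vs 23), 200 replicates, reporting the Mann-Whitney
rejection rate and how often the ROC Youden cut-off lands between the
two group medians. Writes results/statistical_calibration.csv.

Run from the repository root:  python analysis/04_statistical_calibration.py
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from aortaflow.cohort_stats import (
    conover_posthoc,
    kruskal_wallis,
    mann_whitney,
    roc_youden,
)
from aortaflow.synthetic import lognormal_sigma


def type_one_error(seed: int, reps: int = 500):
    rng = np.random.default_rng(seed)
    sigma = lognormal_sigma(10.0, 5.0)
    mw = kw = conover = pairs = 0
    for _ in range(reps):
        draws = [10.0 * np.exp(sigma * rng.standard_normal(n)) for n in (50, 50)]
        mw += mann_whitney(*draws).p_value < 0.05
        groups = {
            name: 10.0 * np.exp(sigma * rng.standard_normal(20))
            for name in ("a", "b", "c")
        }
        kw += kruskal_wallis(groups).p_value < 0.05
        for res in conover_posthoc(groups):
            conover += res.p_value < 0.05
            pairs += 1
    return {"mann_whitney": mw / reps, "kruskal_wallis": kw / reps,
            "conover": conover / pairs}


def power_and_cutoff(med1, iqr1, med2, iqr2, seed: int, reps: int = 200):
    rng = np.random.default_rng(seed)
    s1, s2 = lognormal_sigma(med1, iqr1), lognormal_sigma(med2, iqr2)
    rej = between = 0
    for _ in range(reps):
        x = med1 * np.exp(s1 * rng.standard_normal(10))
        y = med2 * np.exp(s2 * rng.standard_normal(23))
        rej += mann_whitney(x, y).p_value < 0.05
        pooled = np.concatenate([x, y])
        labels = np.r_[np.zeros(10, int), np.ones(23, int)]
        cut = roc_youden(pooled, labels).youden_cutoff
        between += med1 < cut < med2
    return rej / reps, between / reps


def main(seed: int = 20240915) -> None:
    t1 = type_one_error(seed)
    fd_power, fd_between = power_and_cutoff(16, 5, 23, 10, seed + 1)
    sfrr_power, sfrr_between = power_and_cutoff(7, 6, 11, 10, seed + 2)

    rows = [
        {"quantity": "type1_mann_whitney", "value_pct": 100 * t1["mann_whitney"]},
        {"quantity": "type1_kruskal_wallis", "value_pct": 100 * t1["kruskal_wallis"]},
        {"quantity": "type1_conover_pairwise", "value_pct": 100 * t1["conover"]},
        {"quantity": "power_fd_16v23_n10v23", "value_pct": 100 * fd_power},
        {"quantity": "youden_between_fd", "value_pct": 100 * fd_between},
        {"quantity": "power_sfrr_7v11_n10v23", "value_pct": 100 * sfrr_power},
        {"quantity": "youden_between_sfrr", "value_pct": 100 * sfrr_between},
    ]
    table = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/statistical_calibration.csv", index=False,
                 float_format="%.4g")

    print("type-I error at alpha = 0.05 (500 null replicates):")
    for key, val in t1.items():
        print(f"  {key:<16} {100 * val:.1f}%")
    print("\npower at cohort-scale effect sizes (n = 10 vs 23, 200 replicates):")
    print(f"  FDsavg 16 vs 23:  reject {100 * fd_power:.0f}%, "
          f"Youden cut-off between medians {100 * fd_between:.0f}%")
    print(f"  sFRR    7 vs 11:  reject {100 * sfrr_power:.0f}%, "
          f"Youden cut-off between medians {100 * sfrr_between:.0f}%")
    print("\nthe sFRR spreads overlap heavily at these sample sizes: the low"
          "\npower there reflects the group overlap, not a defect of the test.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 20240915)
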