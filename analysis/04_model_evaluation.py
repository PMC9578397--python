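"""Evaluate the fitted model: nonparametric bootstrap and pcVPC.

The bootstrap resamples subjects with replacement and refits, reporting the
convergence success rate and 5th-95th percentile intervals of the
estimates; the prediction-corrected visual predictive check compares
observed concentration percentiles with 90% simulation bands per
time-after-dose bin.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from bdqpk.evaluate import bootstrap, pc_vpc
from bdqpk.model import final_model

fit_step = importlib.import_module("02_fit_final_model")

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20201001
N_RESAMPLES = 40  # scaled-down resample count for a single-CPU run
N_SIM = 400


def main() -> None:
    records, _, _ = fit_step.load_prepared()
    m = final_model()  # reference estimates as the evaluated model

    boot = bootstrap(records, m, n_resamples=N_RESAMPLES, seed=SEED,
                     maxfev=0, polish_maxfev=700, polish_xtol=5e-3, polish_ftol=2e-3, stationarity_tol=1.0)
    boot.summary().to_csv(OUT / "bootstrap_summary.csv")
    print(f"bootstrap ({N_RESAMPLES} resamples): success rate {boot.success_rate:.0f}%")
    print(boot.summary().round(3).to_string())

    summary = pc_vpc(records, m, n_sim=N_SIM, bins=8, seed=SEED, lod=0.024)
    summary.table.to_csv(OUT / "vpc.csv", index=False)
    print(f"pcVPC: {100 * summary.coverage():.0f}% of bin-percentile points inside 90% bands")

    fig, ax = plt.subplots(figsize=(7, 5))
    t = summary.table
    for pct, color in ((5.0, "tab:blue"), (50.0, "tab:red"), (95.0, "tab:blue")):
        sub = t[t["percentile"] == pct]
        mid = (sub["t_lo"] + sub["t_hi"]) / 2
        ax.fill_between(mid, sub["sim_lo"], sub["sim_hi"], alpha=0.25, color=color)
        ax.plot(mid, sub["observed"], "o-", color=color, label=f"observed p{pct:.0f}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "vpc.png", dpi=120)
    print(f"wrote {OUT/'vpc.png'}")


if __name__ == "__main__":
    main()
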