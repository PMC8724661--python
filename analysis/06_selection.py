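"""Model-selection consistency study: generate cohorts with a random
intercept and two random slopes, fit all four candidate structures per
replicate, and record which one each criterion picks.

Writes results/selection.csv.  Runtime: about 80 seconds per replicate on
one CPU (four fits plus likelihood evaluation each).
"""

from pathlib import Path

from qlmm import CohortConfig, SAEMConfig, TruthRecord
from qlmm.simulate import SELECTION_PSI, selection_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 47


def main():
    table = selection_experiment(
        truth=TruthRecord(psi_true=SELECTION_PSI),
        cfg=CohortConfig(n_subjects=60),
        replicates=6,
        fit_cfg=SAEMConfig(W=100, c=0.4, m=5, burn_in_per_iteration=8),
        seed=SEED,
        loglik_draws=600,
    )
    table.to_csv(RESULTS / "selection.csv", index=False)
    print(table.to_string(index=False))
    print(f"AIC picks the full structure in "
          f"{100 * table.attrs['aic_win_fraction']:.0f}% of replicates")
    print(f"wrote {RESULTS / 'selection.csv'}")


if __name__ == "__main__":
    main()
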