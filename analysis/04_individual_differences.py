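"""Correlate per-subject FAA and synchrony summaries with covariates.

For each subject, the mean FAA and the lag-2 CCC in the "Gaze and Hands"
condition are correlated (Pearson, Benjamini-Hochberg corrected) with the
individual-difference table from 01_simulate_dyads.py; a winsorized
sensitivity variant accompanies each family.  On synthetic data the
covariates are independent of the EEG, so corrected p-values should be
unremarkable — this run demonstrates the procedure, not a finding.
"""

from pathlib import Path

import pandas as pd

from dyadsync import correlate_individual_differences

ROOT = Path(__file__).resolve().parents[1]
CONDITION = "Gaze and Hands"
LAG = 2

def main() -> None:
    pdir = ROOT / "results" / "pipeline"
    cov = pd.read_csv(ROOT / "results" / "covariates.csv")
    out_rows = []
    faa = pd.read_csv(pdir / "faa_epochs.csv")
    faa_summary = (
        faa[(faa.condition == CONDITION) & faa.valid]
        .groupby("subject_id")["faa"].mean().rename("value").reset_index()
    )
    ccc = pd.read_csv(pdir / "ccc_subject.csv")
    ccc_summary = (
        ccc[(ccc.condition == CONDITION) & (ccc.lag_bins == LAG)]
        [["subject_id", "ccc"]].rename(columns={"ccc": "value"})
    )
    for name, summary in (("faa", faa_summary), (f"ccc_lag{LAG}", ccc_summary)):
        for wins in (False, True):
            res = correlate_individual_differences(summary, cov, winsorize=wins)
            res.insert(0, "summary", name)
            out_rows.append(res)
            n_sig = int((res["p_fdr"] < 0.05).sum())
            print(f"{name} ({'winsorized' if wins else 'raw'}): "
                  f"{len(res)} covariates, {n_sig} significant after FDR")
    table = pd.concat(out_rows, ignore_index=True)
    table.to_csv(ROOT / "results" / "correlations.csv", index=False)
    print("wrote results/correlations.csv")


if __name__ == "__main__":
    main()
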