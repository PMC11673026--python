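"""Fit the condition/time and condition/lag mixed models on pipeline output.

FAA model: epoch-level FAA ~ condition x (linear + quadratic time),
random intercept per person; marginal means per condition and linear
trends in 30 s increments.  CCC model: subject-level CCC ~ condition x
lag with FDR-corrected pairwise condition contrasts within each lag.
Tables land in results/models/.
"""

from pathlib import Path

import pandas as pd

from dyadsync import fit_ccc_model, fit_faa_model

ROOT = Path(__file__).resolve().parents[1]

def main() -> None:
    pdir = ROOT / "results" / "pipeline"
    if not pdir.exists():
        raise SystemExit("run analysis/02_run_pipeline.py first")
    out = ROOT / "results" / "models"
    out.mkdir(parents=True, exist_ok=True)

    faa = pd.read_csv(pdir / "faa_epochs.csv")
    faa_res = fit_faa_model(faa)
    faa_res.f_table.to_csv(out / "model_faa.csv", index=False)
    faa_res.emm.to_csv(out / "model_faa_emm.csv", index=False)
    faa_res.trends.to_csv(out / "model_faa_trends.csv", index=False)
    print(f"FAA model ({faa_res.optimizer}, converged={faa_res.converged}, "
          f"n={faa_res.n_obs} epochs)")
    print(faa_res.f_table.to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}"))

    ccc = pd.read_csv(pdir / "ccc_subject.csv")
    ccc_res = fit_ccc_model(ccc)
    ccc_res.f_table.to_csv(out / "model_ccc.csv", index=False)
    ccc_res.emm.to_csv(out / "model_ccc_emm.csv", index=False)
    ccc_res.contrasts.to_csv(out / "contrasts.csv", index=False)
    print(f"\nCCC model ({ccc_res.optimizer}, converged={ccc_res.converged}, "
          f"n={ccc_res.n_obs} subject x condition x lag cells)")
    print(ccc_res.f_table.to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
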