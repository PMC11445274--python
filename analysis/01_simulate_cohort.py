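"""Generate the default phantom cohort and summarize its composition.

30 patients (3 included twice, 33 cases), each with a contrast-enhancing
rim of ~5000 voxels carrying planted, spatially contiguous TP and PsP
territories (50% TP), multimodal channels and a registered follow-up scan.
Writes results/cohort_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from svxresp.synthetic import default_cohort_config, generate_cohort

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cases = generate_cohort(default_cohort_config(seed=SEED))
    rows = []
    for b in cases:
        cet = b.cet_mask
        rows.append(
            {
                "case_id": b.case_id,
                "patient_id": b.patient_id,
                "n_cet_voxels": int(cet.sum()),
                "planted_tp_fraction": round(b.truth_labels.tp_fraction(), 4),
                "mean_tbr_tp": round(
                    float(
                        (b.channels["PET_raw"][b.truth_labels.tp_mask]).mean() / 100.0
                    ),
                    3,
                ),
                "mean_tbr_psp": round(
                    float(
                        (b.channels["PET_raw"][b.truth_labels.psp_mask]).mean() / 100.0
                    ),
                    3,
                ),
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "cohort_summary.csv", index=False)

    n_repeat = (df.groupby("patient_id").size() > 1).sum()
    print(f"{len(df)} cases from {df['patient_id'].nunique()} patients "
          f"({n_repeat} patients included twice)")
    print(f"CET size: median {int(df['n_cet_voxels'].median())} voxels "
          f"(range {df['n_cet_voxels'].min()}-{df['n_cet_voxels'].max()})")
    print(f"planted TP fraction: {df['planted_tp_fraction'].mean():.3f} "
          f"(target 0.5)")
    print(f"planted TBR contrast: TP {df['mean_tbr_tp'].mean():.2f} vs "
          f"PsP {df['mean_tbr_psp'].mean():.2f}")
    print(f"-> {RESULTS / 'cohort_summary.csv'}")


if __name__ == "__main__":
    main()
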