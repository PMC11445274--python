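"""Validate the DSC leakage correction on simulated voxel curves.

Simulates 100 voxels following the linear leakage model (K1 in [0.5, 1.5],
K2 in [0, 0.1], 1% peak noise) against a clean gamma-variate reference
tissue, refits K1/K2 per voxel and compares corrected CBV with truth.
Writes results/cbv_recovery.json.
"""

import json
from pathlib import Path

import numpy as np

from svxresp.perfusion import _cumtrapz, gamma_variate, leakage_corrected_cbv

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rng = np.random.default_rng(SEED)
    t = np.arange(60) * 1.5
    ref = 0.01 * gamma_variate(t)
    k1 = rng.uniform(0.5, 1.5, 100)
    k2 = rng.uniform(0.0, 0.1, 100)
    curves = k1[:, None] * ref - k2[:, None] * _cumtrapz(ref, t)
    curves += 0.01 * ref.max() * rng.standard_normal(curves.shape)

    dr2 = np.concatenate([np.broadcast_to(ref, (125, t.size)), curves]).reshape(
        225, 1, 1, t.size
    )
    mask = np.zeros((225, 1, 1), bool)
    mask[:125] = True
    fit = leakage_corrected_cbv(dr2, mask, t)

    cbv_true = k1 * np.trapezoid(ref, t)
    summary = {
        "n_voxels": 100,
        "k1_median_rel_err_pct": round(
            100 * float(np.median(np.abs(fit.k1_map[125:, 0, 0] - k1) / k1)), 3
        ),
        "k2_median_rel_err_pct": round(
            100
            * float(
                np.median(
                    np.abs(fit.k2_map[125:, 0, 0] - k2) / np.maximum(k2, 1e-12)
                )
            ),
            3,
        ),
        "cbv_median_rel_err_pct": round(
            100 * float(np.median(np.abs(fit.cbv[125:, 0, 0] - cbv_true) / cbv_true)),
            3,
        ),
        "uncorrected_cbv_median_bias_pct": round(
            100
            * float(np.median((fit.cbv_uncorrected[125:, 0, 0] - cbv_true) / cbv_true)),
            2,
        ),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "cbv_recovery.json").write_text(json.dumps(summary, indent=2) + "\n")
    print("leakage-model parameter recovery (100 simulated voxels):")
    for k, v in summary.items():
        print(f"  {k}: {v}")
    print("uncorrected CBV underestimates leaky voxels; the K2 term restores it")
    print(f"-> {RESULTS / 'cbv_recovery.json'}")


if __name__ == "__main__":
    main()
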