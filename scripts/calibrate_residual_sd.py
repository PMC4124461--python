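"""Derive the default residual SD of the synthetic cohort generator.

The burden analysis reports, at n = 72, a score-coefficient standard error
of 1.684 years and a partial R^2 near 0.067.  Under Hardy-Weinberg the
Total SNP Risk score has variance

    Var(TSR) = sum_j w_j^2 * 2 p_j (1 - p_j)

and, because the panel genotypes are independent of repeat length, the
OLS standard error of the score coefficient is approximately

    SE(b_TSR) = sigma / (sqrt(n) * sd(TSR)).

Solving SE(b_TSR) = 1.684 for sigma gives the default residual SD.  This
is a closed-form calibration: no simulation output feeds back into it.

Run:  python scripts/calibrate_residual_sd.py
"""

import numpy as np

from fxpoi.burden import DEFAULT_PANEL

TARGET_SE = 1.684
TARGET_PARTIAL_R2 = 0.067
N = 72
B_TSR = -3.710


def main() -> None:
    p = np.array([s.effect_allele_frequency for s in DEFAULT_PANEL])
    w = np.abs([s.effect_size for s in DEFAULT_PANEL])
    var_tsr = float(np.sum(w**2 * 2 * p * (1 - p)))
    sd_tsr = np.sqrt(var_tsr)
    sigma = TARGET_SE * np.sqrt(N) * sd_tsr
    print(f"Var(TSR) under HWE      : {var_tsr:.4f}  (sd {sd_tsr:.4f})")
    print(f"sigma matching SE={TARGET_SE}: {sigma:.3f} years")
    # implied expected partial R^2 at that sigma (t^2 / (t^2 + df_resid))
    t2 = (B_TSR / (sigma / (np.sqrt(N) * sd_tsr))) ** 2
    df_resid = N - 4
    print(f"implied partial R^2     : {t2 / (t2 + df_resid):.4f} "
          f"(target ~{TARGET_PARTIAL_R2})")
    print(f"chosen default residual_sd = {round(sigma, 1)}")


if __name__ == "__main__":
    main()
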