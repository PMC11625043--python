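"""Speech reception threshold from a logistic psychometric function,
plus digit-span and Stroop scoring.
"""

import numpy as np

from hemilat import PsychometricData, fit_logistic, score_digit_span, score_stroop, threshold_across_conditions
from hemilat.psychometrics import DEFAULT_SNR_LEVELS, logistic

rng = np.random.default_rng(6)
snrs = np.asarray(DEFAULT_SNR_LEVELS)

fits = []
for spatial, true_alpha in (("colocated", -3.5), ("separated", -6.0)):
    p_true = logistic(snrs, true_alpha, 1.2)
    n_correct = rng.binomial(20, p_true)  # 20 sentences per SNR level
    fit = fit_logistic(PsychometricData(snrs, np.full(5, 20), n_correct))
    fits.append(fit)
    print(f"{spatial:10s} true alpha {true_alpha:+.1f} dB -> fitted {fit.alpha:+.2f} dB "
          f"(beta {fit.beta:.2f}, converged={fit.converged})")

print(f"task threshold (mean over spatial conditions): {threshold_across_conditions(fits):.2f} dB")

span_fwd = score_digit_span([(3, [True, True]), (4, [True, False]), (5, [True, True]),
                             (6, [False, True]), (7, [False, False])])
span_bwd = score_digit_span([(2, [True, True]), (3, [True, True]), (4, [False, False])])
print(f"digit span: forward {span_fwd} + backward {span_bwd} = {span_fwd + span_bwd}")
print(f"Stroop interference: {score_stroop(1.82, 2.05):.2f} s (larger = poorer inhibition)")
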