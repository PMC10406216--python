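"""The two analytic reference methods: RVT*RRF and linear regression.

RVT (respiratory volume per time) is the breath-wise peak-trough belt
amplitude over the breath period. Convolved with the respiratory
response function RRF(t) = 0.6 t^2.1 e^(-t/1.6) - 0.0023 t^3.54 e^(-t/4.25)
and aligned against the measured PETCO2 it gives the classical estimate;
the LR baseline is a single affine map fitted to training recordings.
"""

import numpy as np

from respco2 import (SimParams, compute_rvt, extract_petco2, lowpass, lr_fit,
                     preprocess_pipeline, rrf, rvtrrf_predict,
                     simulate_recording)
from respco2.train_eval import pearson_r

t_peak = 3.072
print(f"RRF rises to its positive lobe maximum {rrf(t_peak):.3f} at "
      f"t = {t_peak:.2f} s and undershoots afterwards (min "
      f"{rrf(np.arange(0, 60, 0.01)).min():.3f}).")

proc, _ = preprocess_pipeline(simulate_recording(SimParams(seed=3)).recording)
rvt = compute_rvt(proc.resp)
print(f"RVT over the recording: mean {rvt.values.mean():.2f}, "
      f"SD {rvt.values.std():.2f} (normalized belt units per second)")

truth = extract_petco2(proc.co2)
est = rvtrrf_predict(proc.resp, truth)
n = min(est.series.n, truth.series.n)
print(f"RVTRRF vs measured PETCO2: r = "
      f"{pearson_r(est.series.values[:n], truth.series.values[:n]):.3f} "
      f"(lag- and sign-aligned against the truth, so always positive)")

model = lr_fit([proc])
print(f"LR fit on the same recording: CO2'(t) = {model.beta:.3f} * Resp(t) "
      f"+ {model.intercept:.3f} — the negative slope reflects the")
print("respiration-CO2 anticorrelation; an affine map cannot change |r|.")
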