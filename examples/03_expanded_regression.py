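"""Recover a lag-specific evidence correlate with the expanded regression.

A momentary-evidence effect is embedded at 120 ms after each dot onset with
a theoretical signal correlation of 0.1.  The expanded design gives every
(trial, dot) pair one row at a fixed latency from that dot's onset —
excluding everything within 200 ms of the response — so within-trial
evidence fluctuations are pooled across trials.  The z-scoring contract
makes the fitted coefficient read as a correlation.
"""

from evreg.calibration import evidence_recovery

rec = evidence_recovery(seed=8, correlation=0.1, lag_ms=120)
print(f"rows entering the regression at the peak: {rec['n_rows']}")
print(f"recovered peak latency:  {rec['peak_lag_ms']} ms (truth: 120 ms)")
print(f"recovered coefficient:   {rec['coefficient']:.4f} "
      f"(truth: {rec['target_correlation']}, SE ~ {rec['se']:.4f})")
print()
print("The peak sits at the embedded lag and the coefficient matches the")
print("analytic correlation within sampling error — the regression reads")
print("out exactly the ground truth that was planted in the signal.")
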