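"""How decoding quality depends on analysis-window duration.

Runs the eight-window scheme (four 0.5-s, two 1-s, one 2-s, one 4-s window)
for one subject under 5-fold cross-validation with all three decoders and
prints the per-duration accuracy and false-positive ratio.
"""

from mibci import bandpass, duration_summary, generate_session, run_sweep, segment
from mibci.synthdata import SimulationConfig

epochs = segment(bandpass(generate_session(SimulationConfig(seed=2))))
results = run_sweep(
    {"S01": epochs}, regimes=("cv_5fold",), positive_class="mi", seed=2
)
summary = duration_summary(results)
print(summary[["classifier", "duration_s", "accuracy", "fpr"]].to_string(index=False))
print()
print("Longer windows give steadier band-power (log-variance) estimates, so")
print("accuracy rises and the false-positive ratio falls from 0.5 s to 4 s —")
print("the price is a slower system response.")
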