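"""Simulate one cue-paced motor-imagery calibration session.

Builds a default 11-channel session (35 imagery cues, 10-s trial cycles,
mu/beta sources over C3/C4 with 50% contralateral desynchronization) and
prints what landed in the recording.
"""

import numpy as np
from scipy import signal

from mibci import SimulationConfig, generate_session

cfg = SimulationConfig(seed=1)
raw = generate_session(cfg)

labels = [lab for _, lab in raw.events]
print(f"recording: {raw.n_channels} channels x {raw.duration_s:g} s at {raw.fs:g} Hz")
print(f"events: {len(raw.events)} ({labels.count('mi')} imagery cues, "
      f"{labels.count('rest')} rest markers)")

# The fingerprint of event-related desynchronization: during imagery the
# C3-overlying mu rhythm loses power relative to the break intervals.
c3 = raw.channel_labels.index("C3")
fs = raw.fs


def mu_power(x):
    f, p = signal.welch(x, fs=fs, nperseg=512)
    return p[(f >= 8) & (f <= 13)].sum()


cue_p, rest_p = [], []
for onset, lab in raw.events:
    if lab == "mi":
        cue_p.append(mu_power(raw.samples[c3, onset + int(2 * fs): onset + int(6 * fs)]))
        rest_p.append(mu_power(raw.samples[c3, onset + int(6 * fs): onset + int(10 * fs)]))
ratio = np.mean(cue_p) / np.mean(rest_p)
print(f"C3 mu-band power, imagery vs rest: ratio {ratio:.2f}")
print("(< 1 means the contralateral rhythm desynchronizes during imagery;")
print(" at the default 5 dB SNR the background dilutes the configured 0.5)")
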