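"""Reproduce the complete study design in one call.

Simulates a six-subject cohort and runs the full subject x classifier x
window x regime sweep (288 cells), writing results.csv, a per-duration
summary, a trend figure and a manifest into ./mibci_run/.
"""

from mibci import ExperimentConfig, run_experiment
from mibci.pipeline import SUMMARY_TXT

cfg = ExperimentConfig(n_subjects=6, global_seed=0, output_dir="mibci_run")
out = run_experiment(cfg)

print(f"artifacts in {out}/:")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")
print()
print((out / SUMMARY_TXT).read_text())
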