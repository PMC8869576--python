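"""Validate staged output against a reference hypnogram.

Stages a simulated night and prints confusion matrices at two resolutions:
wake vs sleep over all epochs, and light/deep/REM over the epochs both
hypnograms score as sleep.
"""

from somnograph import SimProfile, confusion, simulate_night, stage_night

epochs, reference = simulate_night(SimProfile.well_separated(), seed=3)
predicted = stage_night(epochs)

for scheme in ("sleep_wake", "light_deep_rem"):
    cm = confusion(reference, predicted, scheme)
    print(f"\n{scheme} (rows = reference, columns = predicted)")
    header = "".join(f"{label:>8s}" for label in cm.labels)
    print(" " * 8 + header)
    for label, row in zip(cm.labels, cm.counts):
        print(f"{label:>8s}" + "".join(f"{int(c):8d}" for c in row))
    print(f"accuracy: {cm.accuracy_pct:.2f} % of {cm.total} epochs")

print("\n(the diagonal holds correctly staged epochs; off-diagonal cells show"
      " which stages the classifier confuses)")
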