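"""Activation thresholds of a toy fiber and a recruitment/AUC evaluation.

A 21-node myelinated fiber passes 1 mm from a point source.  The threshold
amplification factor (the stimulus current that just elicits a spike under
the cathodic-first biphasic pulse) is found by doubling + bisection; a
branch of such thresholds defines the recruitment curve, and target vs
non-target recruitment defines the ROC/AUC selectivity.
"""

import numpy as np

import vestim as vs
from vestim.evaluation import recruitment_curve
from vestim.neuron import NeuronParams

xs = (np.arange(21) - 10) * 300e-6
waveform = vs.biphasic_waveform(200e-6, 30e-6, cathodic_first=True)
params = NeuronParams()

print("distance -> threshold (strength of electrode-nerve coupling):")
thresholds = {}
for z in (0.5e-3, 1e-3, 2e-3):
    u = 1.0 / (4 * np.pi * 0.3) / np.sqrt(xs**2 + z**2)
    t = vs.find_threshold(u, waveform, params).threshold
    thresholds[z] = t
    print(f"  fiber at {z * 1e3:.1f} mm: threshold {t * 1e3:.3f} mA")

print("strength-duration (longer phases need less current):")
u = 1.0 / (4 * np.pi * 0.3) / np.sqrt(xs**2 + 1e-3**2)
for T in (50e-6, 100e-6, 200e-6, 400e-6):
    t = vs.find_threshold(u, vs.biphasic_waveform(T, 30e-6), params).threshold
    print(f"  {T * 1e6:.0f} us phase: {t * 1e3:.3f} mA")

target = recruitment_curve(np.array([0.6, 0.8, 1.0, 1.3]) * 1e-3, branch="target")
non = recruitment_curve(np.array([1.1, 1.5, 2.0, 2.4]) * 1e-3, branch="neighbor")
auc = vs.roc_auc(target, [non])
a80 = vs.amplitude_for_recruitment(target, 0.8)
q = vs.charge_per_pulse(waveform, a80)
print(f"selectivity: AUC {auc:.3f}, 80% of the target at {a80 * 1e3:.2f} mA, "
      f"{q['cathodic_C'] * 1e9:.0f} nC per phase")
print("-> AUC 1 would mean every target fiber fires before any neighbor fiber.")
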