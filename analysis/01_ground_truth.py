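"""Build the analytic ground truth: inflow waveform, harmonics, profile, WSS.

Writes the waveform CSV and summary figures under results/, and prints the
key scales of the flow (peak flow, Womersley number, peak wall shear
stress) that every later comparison is measured against.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from flowres.flow_model import (
    BLOOD,
    VesselModel,
    WomersleyField,
    analytic_wss,
    decompose,
    make_waveform,
    save_waveform_csv,
    womersley_number,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
FIGS = RESULTS / "figures"
FIGS.mkdir(parents=True, exist_ok=True)

vessel = VesselModel()
waveform = make_waveform()
decomp = decompose(waveform, 8)
field = WomersleyField(decomp, vessel, BLOOD)
save_waveform_csv(waveform, RESULTS / "inflow_waveform.csv")

alpha = womersley_number(vessel.radius, decomp.fundamental_angular_frequency,
                         BLOOD.kinematic_viscosity)
t = np.linspace(0, waveform.period, 400)
tau = analytic_wss(decomp, vessel, BLOOD, t)
rec = decomp.reconstruct(waveform.sample_times)
rms = np.sqrt(np.mean((rec - waveform.flow_values) ** 2)) / waveform.peak_flow

print(f"vessel: straight tube, diameter {2 * vessel.radius * 1e3:.2f} mm")
print(f"waveform: period {waveform.period} s, peak flow {waveform.peak_flow:.3e} m^3/s")
print(f"harmonics: K=8, reconstruction RMS {100 * rms:.2f}% of peak flow")
print(f"Womersley number (fundamental): {alpha:.2f}")
print(f"wall shear stress over the cycle: min {tau.min():.3f}, max {tau.max():.3f} Pa")

fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
axes[0].plot(waveform.sample_times, 1e6 * waveform.flow_values, ".-")
axes[0].set(xlabel="t (s)", ylabel="Q (mL/s)", title="Inflow waveform")
r = np.linspace(0, vessel.radius, 200)
for frac, label in ((0.17, "peak systole"), (0.05, "upstroke"), (0.6, "diastole")):
    axes[1].plot(1e3 * r, field.profile(r, frac), label=label)
axes[1].set(xlabel="r (mm)", ylabel="u (m/s)", title="Velocity profiles")
axes[1].legend(fontsize="small")
axes[2].plot(t, tau)
axes[2].set(xlabel="t (s)", ylabel="wall shear stress (Pa)", title="Analytic WSS")
fig.tight_layout()
fig.savefig(FIGS / "01_ground_truth.png", dpi=120)
print(f"figure: {FIGS / '01_ground_truth.png'}")
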