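"""Inlet-plane geometry versus scan resolution.

Segments each virtual scan at the permissive (0.25) and the unbiased (0.5)
magnitude thresholds and reports the equivalent diameter of the inlet
plane, averaged over 10 seeded grid offsets, in the layout of the
published diameter table (resolution, area, equivalent diameter).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flowres.flow_model import BLOOD, VesselModel, WomersleyField, decompose, make_waveform
from flowres.geometry import PlaneSpec, equivalent_diameter, segment, slice_area
from flowres.virtual_scanner import AcquisitionSettings, acquire

ROOT = Path(__file__).resolve().parents[1]
(ROOT / "results").mkdir(exist_ok=True)

vessel = VesselModel()
field = WomersleyField(decompose(make_waveform(), 8), vessel, BLOOD)
plane = PlaneSpec(-0.0125)
offsets = np.random.default_rng(0).random((10, 3))

rows = []
for res in (4.0, 3.0, 2.0, 1.5):
    for thr in (0.25, 0.5):
        areas = []
        for off in offsets:
            s = AcquisitionSettings(voxel_size=res, grid_offset=tuple(off))
            vox = acquire(field, vessel, s, 0.9, frame_times=[0.16])
            areas.append(slice_area(segment(vox, thr), plane))
        area = float(np.mean(areas))
        rows.append(
            dict(
                resolution_mm=res,
                threshold=thr,
                area_mm2=round(area * 1e6, 2),
                equivalent_diameter_cm=round(equivalent_diameter(area) * 1e2, 4),
            )
        )

df = pd.DataFrame(rows)
df.to_csv(ROOT / "results" / "inlet_diameters.csv", index=False)
print(df.to_string(index=False))
print(f"\ntrue diameter: {2 * vessel.radius * 1e2:.4f} cm")
print("threshold 0.25 dilates the coarse scans; 0.5 stays within one voxel of truth")
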