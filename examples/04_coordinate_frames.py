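"""Fiducial-defined head frames and transforms between vendor conventions.

From the three anatomical landmarks (nasion, left/right pre-auricular) we
build the CTF-style ALS frame and the Neuromag-style RAS frame, and map
points between them.  In ALS the nasion lands on +x and the ear midpoint at
the origin; in RAS the nasion lands on +y and the ears on the x axis.
"""
import numpy as np

from megbids import Fiducials, between_frames, convert_units, frame_from_fiducials

fid = Fiducials(nas=[10.2, 0.4, 0.1], lpa=[-0.3, 7.5, -0.2], rpa=[0.2, -7.3, 0.0],
                units="cm")

# the transform takes points in the fiducials' native units (cm here) and
# yields head-frame coordinates in metres
als = frame_from_fiducials(fid, "CTF")
print("ALS nasion      :", np.round(als.apply(fid.nas), 4), "m  (on +x)")
print("ALS ear midpoint:", np.round(als.apply((fid.lpa + fid.rpa) / 2), 4), "m (origin)")

ras = frame_from_fiducials(fid, "ElektaNeuromag")
print("RAS nasion      :", np.round(ras.apply(fid.nas), 4), "m  (on +y)")

T = between_frames(fid, "CTF", "ElektaNeuromag")
back = between_frames(fid, "ElektaNeuromag", "CTF")
pts = np.array([[0.05, 0.02, 0.11]])
err = np.abs(back.apply(T.apply(pts)) - pts).max()
print(f"ALS→RAS→ALS round-trip error: {err:.2e} m")

print("10 cm in mm:", convert_units([10.0, 0, 0], "cm", "mm")[0])
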