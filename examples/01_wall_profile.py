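"""Build the double-stenosis wall geometry and locate its throats.

The default artery model is a rigid tube of unit radius with two cosine
constrictions on z in [3, 7]; each narrows the lumen to half its radius.
"""

import numpy as np

from stenoflow import StenosisGeometry

geom = StenosisGeometry()  # lambda = 0.5, l = 2, d = 3, L = 10

z = np.linspace(0.0, geom.domain_length, 11)
print("z    :", "  ".join(f"{v:5.1f}" for v in z))
print("h(z) :", "  ".join(f"{v:5.3f}" for v in geom.wall_radius(z)))

print(f"\nstenosed zone: {geom.zone}")
print(f"throat stations: {geom.throat_locations()}")
print(f"lumen radius at the throats: {geom.wall_radius(4.0):.3f}")

# h drops from 1 to 0.5 at z = 4 and z = 6 (a 75% area reduction at each
# throat) and recovers to the unconstricted radius outside [3, 7].
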