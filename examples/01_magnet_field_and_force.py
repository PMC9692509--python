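"""Field and magnetophoretic force of a cuboid permanent magnet.

Evaluates the closed-form Coulombian field of the 1 x 1 x 4 cm NdFeB bar
magnet of protocol 1 and the resulting force on a 7.5 um magnetite
microparticle a few millimetres away.
"""

import numpy as np

from nasomag.magnetics import (MU0, ParticleProps, cuboid_H,
                               magnetophoretic_force, protocol_layout,
                               total_field)

(magnet,) = protocol_layout(1)  # bar magnet, 5 mm behind the septum plane
print(f"remanence |B_r|     : {np.linalg.norm(magnet.remanence):.4f} T")
print(f"magnetization |M|   : {np.linalg.norm(magnet.magnetization):.3e} A/m")

# a point in the release plane (2.5 mm inside the nose), near the vestibule
point = (0.0025, 0.010, 0.025)
H = cuboid_H(point, magnet)
print(f"H at {point} m      : {H} A/m  (|B| = {MU0 * np.linalg.norm(H):.4f} T)")

props = ParticleProps()  # R_p = 7.5 um magnetite
sample = total_field(point, [magnet])
F = magnetophoretic_force(sample, props, mode="high_chi")
drift = np.linalg.norm(F) / (6 * np.pi * 1.9e-5 * props.radius)
print(f"magnetophoretic F   : {F} N")
print(f"drift speed F/(6 pi eta R_p): {drift:.3f} m/s")
print()
print("The drift speed is the terminal velocity the force can impose against")
print("Stokes drag; where it rivals the ~0.5 m/s airflow, the magnet governs")
print("the particle path instead of the stream.")
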