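"""Solvent accessibility: analytic oracle and exposure-based selection.

Computes Shrake-Rupley SASA on a two-sphere toy (where the exact answer is
the spherical-cap formula), then per-residue relative accessibility (RSA)
on a synthetic antigen and the >20% exposed-residue selection used to pick
alanine-scan positions.
"""

import numpy as np

from epidock.sasa import SasaParams, relative_accessibility, select_exposed, shrake_rupley
from epidock.synthetic import make_fv_complex, make_sphere_pair, two_sphere_cap_area

R = 1.7 + 1.4  # carbon vdW + probe radius (A)

# --- two overlapping probe-expanded spheres vs the closed form ------------
sep = 3.1
model = make_sphere_pair(sep)
result = shrake_rupley(model, SasaParams(n_points=960))
expected = 4 * np.pi * R**2 - two_sphere_cap_area(R, sep)
area = next(iter(result.per_atom.values()))
print(f"two-sphere toy, separation {sep} A:")
print(f"  per-sphere SASA  computed {area:8.2f} A^2   analytic {expected:8.2f} A^2")
# the lattice estimate should sit within ~1% of the spherical-cap value

# --- RSA and exposed-residue selection on a synthetic antigen -------------
pose, _, _ = make_fv_complex()
antigen = pose.complex.subset(["A"])
rsa = relative_accessibility(shrake_rupley(antigen, SasaParams(n_points=960)), antigen)
exposed = select_exposed(rsa, threshold_percent=20.0)
print(f"\nsynthetic antigen: {len(rsa.per_residue)} residues, "
      f"{len(exposed)} exposed at RSA > 20%")
print("first five exposed residues (chain:number, RSA%):")
for key in exposed[:5]:
    print(f"  {key[0]}:{key[1]}  {rsa.per_residue[key].rsa:6.1f}%")
# exposed residues are the candidates an alanine scan would mutate
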