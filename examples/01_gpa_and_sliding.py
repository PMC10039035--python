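"""Joint Procrustes superimposition with sliding semilandmarks.

Generates a 12-specimen synthetic otolith-system population (22 single
landmarks + 86 semilandmarks per specimen), superimposes all configurations
jointly, lets the semilandmarks slide along their curves to minimize
thin-plate-spline bending energy, and prints the alignment diagnostics.
"""

import numpy as np

from otolith import PopulationSpec, generate_population, gpa, slide_semilandmarks
from otolith.tps import total_bending_energy

specimens, _ = generate_population(PopulationSpec(seed=42, generate_meshes=False))
aligned = gpa([s.config for s in specimens])
print(f"GPA: n={aligned.n} specimens, k={aligned.k} landmarks, "
      f"{aligned.iterations} iterations, converged={aligned.converged}")
print(f"centroid sizes (mm): {np.round(aligned.centroid_sizes, 2)}")

energy_before = total_bending_energy(aligned)
slid = slide_semilandmarks(aligned)
energy_after = total_bending_energy(slid)
print(f"total bending energy before sliding: {energy_before:.6f}")
print(f"total bending energy after sliding:  {energy_after:.6f}")
print("Sliding re-parametrizes the semilandmark curves so that the remaining")
print("shape differences are not artifacts of equidistant point placement;")
print("the energy drop shows how much placement artifact was removed.")
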