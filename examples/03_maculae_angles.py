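"""Estimating maculae orientation from bony landmark planes.

The orientation of each otolith organ's sensory epithelium (macula) is
approximated by planes through surrounding bony landmarks (LM2/4/6 for the
utricular macula, LM8-10 or a spherical-recess selection for the saccular
macula).  The generator builds macular planes offset 4.6 degrees from the
bony planes, so the table below shows how well each bony pairing recovers
the true orientation.
"""

from otolith import PopulationSpec, generate_population, maculae_orientation_analysis

specimens, _ = generate_population(PopulationSpec(seed=3, generate_meshes=False))
table, summary, fit = maculae_orientation_analysis(
    [s.config for s in specimens],
    macular_surfaces={s.specimen_id: s.macular_surfaces for s in specimens},
    recess_selections={s.specimen_id: s.recess_selection for s in specimens},
)
print("approximation angle (degrees) between bony-derived and macular planes:")
print(summary.round(2).to_string(index=False))
print(f"\ninter-macular angle regression (bony on true): "
      f"R^2 = {fit.r_squared:.3f}, p = {fit.p_value:.4f}")
print("Means near 4.6 degrees show the bony planes track the built-in offset;")
print("the regression shows bony inter-plane angles predict the true ones.")
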