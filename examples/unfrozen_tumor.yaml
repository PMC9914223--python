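# Repository-default problem: unfrozen tumor tissue, pure conduction,
# phi = 100 W/m^2 on a 7 mm slab held at T_i = 40 C.
problem:
  tissue: unfrozen_tumor
  blood: {perfusion_rate: 0.0, blood_specific_heat: 3640.0, arterial_temperature: 37.0}
  sources: {metabolic_heat: 0.0, surface_flux: 100.0}
  geometry: {thickness: 0.007, far_boundary: dirichlet_initial}
  initial_temperature: 40.0
scheme_order: 10
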