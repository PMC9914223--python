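# Frozen-tissue preset (fast conduction, alpha ~ 1.8e-6 m^2/s), as used
# for the far-boundary flux vs thickness study.
problem:
  tissue: frozen_tumor
  blood: {perfusion_rate: 0.0, blood_specific_heat: 3640.0, arterial_temperature: 37.0}
  sources: {metabolic_heat: 0.0, surface_flux: 100.0}
  geometry: {thickness: 0.003, far_boundary: dirichlet_initial}
  initial_temperature: 40.0
scheme_order: 10
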