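# Schematic (theoretical) eye model registry.
#
# Each entry defines the corneal subsystem of a classical reduced eye:
#   n_a          refractive index of air (always 1.0)
#   n_c          corneal refractive index
#   n_ha         aqueous-humor refractive index
#   e_c_model_mm central corneal thickness used in theoretical simulations (mm)
#   n_k_classic  the model's classical single-value keratometric index
#
# The two built-in models below are frozen; additional models may be
# registered at run time from a file of the same shape.

gullstrand:
  n_a: 1.0
  n_c: 1.376
  n_ha: 1.336
  e_c_model_mm: 0.5
  n_k_classic: 1.3315

legrand:
  n_a: 1.0
  n_c: 1.3771
  n_ha: 1.3374
  e_c_model_mm: 0.55
  n_k_classic: 1.3304
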