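# Robust longirostrine morphotype (Stenopterygius-like, specimen fixture M1409).
#
# morphotype: geometric parameters consumed by MorphotypeParams (all mm).
#   label               identifier used in outputs and load-case labels
#   total_skull_length  estimated in-life skull length (preserved cranium is
#                       shorter; see study.preserved_length_mm)
#   rostrum_fraction    share of total length anterior to the orbit; the robust
#                       morphotype carries a longer rostrum relative to its
#                       posterior cranium than the gracile one
#   rostrum_base_height / rostrum_base_width
#                       elliptical snout cross-section at the rostrum base; the
#                       robust snout is deep and wide (robusticity contrast)
#   taper_exponent      rate of snout slenderising toward the tip (1 = linear)
#   cranium_height / cranium_width
#                       box-like posterior cranium envelope
#   orbit_diameter      lateral orbital void diameter (< cranium_height)
#   target_edge_length  mesh granularity; desk-scale default, configurable
#   random_seed         threaded through for interface uniformity (generation
#                       is deterministic)
morphotype:
  label: robust
  total_skull_length: 401.0
  rostrum_fraction: 0.62
  rostrum_base_height: 42.0
  rostrum_base_width: 34.0
  taper_exponent: 1.0
  cranium_height: 80.0
  cranium_width: 72.0
  orbit_diameter: 52.0
  target_edge_length: 6.0
  random_seed: 0

# study: specimen-level context used by the pipeline, not by the mesher.
#   preserved_length_mm  anterior rostrum is broken off in the fossil; the
#                        preserved skull is 185 mm of an estimated 401 mm.
#   load_cases           the robust morphotype has no true anterior-tip bite
#                        case (broken snout): its foremost case is analogous
#                        to the gracile mid-tooth-row bite.
study:
  specimen: M1409
  preserved_length_mm: 185.0
  load_cases: [posterior, mid]
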