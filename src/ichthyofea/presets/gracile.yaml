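# Gracile longirostrine morphotype (Hauffiopteryx-like, specimen fixture M1399).
# Field-by-field documentation in robust.yaml; the contrasts encoded here are
# the printed proportional ones: complete 335 mm skull, larger cranial share
# and larger orbit, and a markedly more slender rostrum (lower base
# height/width and faster taper) than the robust morphotype.
morphotype:
  label: gracile
  total_skull_length: 335.0
  rostrum_fraction: 0.55
  rostrum_base_height: 30.0
  rostrum_base_width: 26.0
  taper_exponent: 1.3
  cranium_height: 82.0
  cranium_width: 74.0
  orbit_diameter: 62.0
  target_edge_length: 6.0
  random_seed: 0

study:
  specimen: M1399
  preserved_length_mm: 335.0
  load_cases: [posterior, mid, anterior]
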