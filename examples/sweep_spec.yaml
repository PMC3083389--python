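# Fixed-lifespan sweep specification for `dispersim sweep --spec`.
# Vessel counts set spatial heterogeneity; lifespans set temporal
# heterogeneity. Per-vessel delivery rescales automatically so the
# system-wide oxygen input is the same in every condition.
vessel_counts: [30, 63, 134, 284, 600]
lifespans: [4, 20, 100, 500]
movement: random
overrides:
  width: 48
  height: 48
  window: 200
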