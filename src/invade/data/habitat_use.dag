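# Causal assumptions for the effect of invasive Opuntia on mammal habitat use.
# One node per variable; "native_plants" is shorthand for the native plant
# community block (grass, shrub, forb and succulent % cover, tree count);
# "habitat_use" stands for the response of whichever model is being fitted
# (occupancy, daily detections, night proportion). Human use of the landscape
# is unobservable and is declared latent: it may never enter an adjustment set.
latent: human_use
exposure: opuntia
outcome: habitat_use

human_use -> opuntia
human_use -> livestock
dist_road -> human_use
dist_river -> human_use
dist_river -> opuntia
dist_river -> native_plants
dist_river -> habitat_use
dist_road -> habitat_use
livestock -> habitat_use
livestock -> native_plants
opuntia -> native_plants
opuntia -> habitat_use
native_plants -> habitat_use
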