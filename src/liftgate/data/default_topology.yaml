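# Default 15-valve / 6-reservoir chip architecture.
#
# This is a SCHEMATIC stand-in, synthetic by construction: it matches the
# device class (valve and reservoir counts, central mixing valves, one
# optical detection channel) but not any specific chip's wiring.
# Layout:
#   R1..R3 (inlet wells) -> inlet valves v1..v3 -> central mixing valves
#   v4..v6 -> transport chain v7..v13 -> detection-feed valve v15 ->
#   detection channel -> outlet R4; waste valve v14 -> outlets R5, R6.
name: default-15v
n_valves: 15
valve_capacity_nl: 10.0
detection_node: detect
reservoirs:
  R1: INLET    # bacteria suspension well
  R2: INLET    # staining dye well
  R3: INLET    # buffer well
  R4: OUTLET   # post-detection waste
  R5: OUTLET   # wash waste
  R6: OUTLET   # auxiliary waste
edges:
  - [R1, v1]
  - [R2, v2]
  - [R3, v3]
  - [v1, v4]
  - [v2, v5]
  - [v3, v6]
  - [v4, v5]
  - [v5, v6]
  - [v4, v7]
  - [v7, v8]
  - [v8, v9]
  - [v9, v10]
  - [v10, v11]
  - [v11, v12]
  - [v12, v13]
  - [v13, v14]
  - [v14, R5]
  - [v14, R6]
  - [v13, v15]
  - [v15, detect]
  - [detect, R4]
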