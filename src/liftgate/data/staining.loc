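# Reference bacteria-staining protocol for the default 15-valve chip.
# Draws bacteria, dye and buffer from inlet wells R1-R3, mixes them in
# the central valves, incubates 20 minutes, then carries the stained
# sample to the optical detection channel.

main:
    call prime
    call mix
    call incubate
    call to_detect
end

def prime:
    # lift the inlet valves so each draws its reagent from the well above
    o 1
    o 2
    o 3
    w 500
end

def mix:
    # push each reagent forward into the central mixing valves
    o 4
    o 5
    o 6
    c 1
    c 2
    c 3
    w 500
    # collect everything in the middle valve
    c 4
    c 6
    w 500
    # rotate the pooled sample back and forth to homogenize
    o 4
    c 5
    w 500
    o 5
    c 4
    w 500
end

def incubate:
    # dye intercalation: 20 min = 1200000 ms
    w 1200000
end

def to_detect:
    # ripple the stained parcel down the transport chain, one valve at a time
    o 4
    c 5
    o 7
    c 4
    o 8
    c 7
    o 9
    c 8
    o 10
    c 9
    o 11
    c 10
    o 12
    c 11
    o 13
    c 12
    o 15
    c 13
    c 15
    w 100
end
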