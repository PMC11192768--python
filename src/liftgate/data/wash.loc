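# Post-experiment wash template for the default 15-valve chip: pulls
# buffer from the R3 well and pumps it through the mixing valves and the
# transport chain into the waste arm (v14 -> R5/R6). Two passes.

main:
    call flush
    call flush
end

def flush:
    o 3
    w 200
    o 6
    c 3
    o 5
    c 6
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
    o 14
    c 13
    c 14
    w 200
end
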