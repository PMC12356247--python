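          Assignment        w1        w2        w3

        R2CA-R2N-R2H    55.700   119.800     8.320
        R1CA-R2N-R2H    55.400   119.800     8.320
        R3CA-R3N-R3H    61.100   119.900     8.000
        R2CA-R3N-R3H    55.700   119.900     8.000
        R4CA-R4N-R4H    57.700   120.300     8.300
        R3CA-R4N-R4H    61.100   120.300     8.300
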