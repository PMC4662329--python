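(ZASU:0.22,(ACOB:0.19,((CAPH:0.09,(CACH:0.07,(CARH:0.06,CASU:0.055):0.012):0.015):0.02,((((BENI:0.012,IITA:0.011):0.004,(MALI:0.013,NIGE:0.012):0.003):0.003,((BRAZ:0.014,YEME:0.013):0.004,(CALI:0.012,UVBF:0.011):0.003):0.002):0.004,(INDI:0.016,UGAN:0.015):0.005):0.06):0.05):0.03);
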