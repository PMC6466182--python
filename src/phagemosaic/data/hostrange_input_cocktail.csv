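# Spot-assay host range: input phages and pooled cocktails at rounds 10/20/30.
# "+" = visible lysis after 16 h; blank = none.
strain,Pa2,phiKZ,RWG,round10,round20,round30
PAO1,+,+,+,+,+,+
PA14,,,,+,+,+
PAK,+,+,,+,+,+
WCC176,,,,,+,+
WCC199,,,,+,+,+
WCC201,,,,+,+,+
WCC205,,,,+,+,+
WCC222,,,,,,+
WCC229,,,,,,+
WCC232,,,,,,+
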