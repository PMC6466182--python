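# Spot-assay host range of individual phages isolated from the round-30 cocktail.
strain,phiPAO1.1,phiPAO1.2,phiPAO1.3,phiPA14.1,phiPA14.2,phiPAK.1,phiPAK.2,phiPAK.3,phi176,phi201,phi229.1,phi229.2
PAO1,+,+,+,+,,+,+,+,+,+,+,+
PA14,,,,+,+,,,,+,+,+,+
PAK,+,+,+,+,,+,+,+,+,+,+,+
WCC176,,,,,,,,,+,,+,+
WCC199,,,,,,,,,+,,+,
WCC201,,,+,+,,,,,+,+,,
WCC205,,,,,,,,,+,,+,+
WCC222,,,,,,,,,+,,+,+
WCC229,,,,,,,,,+,,+,+
WCC232,,,,,,,,,+,,+,+
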