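# Efficiency of plating of the four clinical-strain isolates; "-" = no plaques
# (below 10 pfu/mL on a ~1e8 pfu/mL preparation, hence censor_bound 1e-7).
phage,strain,eop,sd,is_isolation,censor_bound
phi176,PAO1,73.6,5.9,0,
phi176,PA14,9.6e-5,5.4e-4,0,
phi176,PAK,2.7e-5,2.0e-6,0,
phi176,WCC176,1.0,0.1,1,
phi176,WCC199,4.3,1.1,0,
phi176,WCC201,1.8e-6,1.2e-6,0,
phi176,WCC205,3.3,0.4,0,
phi176,WCC222,18.2,1.6,0,
phi176,WCC229,50.0,6.9,0,
phi176,WCC232,39.3,6.7,0,
phi201,PAO1,0.7,0.1,0,
phi201,PA14,1.0e-9,2.4e-8,0,
phi201,PAK,0.1,1.8e-2,0,
phi201,WCC176,-,-,0,1.0e-7
phi201,WCC199,-,-,0,1.0e-7
phi201,WCC201,1.0,0.2,1,
phi201,WCC205,-,-,0,1.0e-7
phi201,WCC222,-,-,0,1.0e-7
phi201,WCC229,-,-,0,1.0e-7
phi201,WCC232,-,-,0,1.0e-7
phi229.1,PAO1,6.7,2.0,0,
phi229.1,PA14,8.3e-5,4.6e-5,0,
phi229.1,PAK,1.3e-6,4.6e-7,0,
phi229.1,WCC176,1.5,0.5,0,
phi229.1,WCC199,3.3e-2,1.2e-2,0,
phi229.1,WCC201,-,-,0,1.0e-7
phi229.1,WCC205,1.4,0.5,0,
phi229.1,WCC222,1.1,0.3,0,
phi229.1,WCC229,1.0,0.4,1,
phi229.1,WCC232,0.1,4.7e-2,0,
phi229.2,PAO1,51.2,11.0,0,
phi229.2,PA14,1.1e-3,4.2e-4,0,
phi229.2,PAK,2.0e-4,4.6e-5,0,
phi229.2,WCC176,7.9,2.7,0,
phi229.2,WCC199,-,-,0,1.0e-7
phi229.2,WCC201,-,-,0,1.0e-7
phi229.2,WCC205,2.6,0.6,0,
phi229.2,WCC222,2.6,0.8,0,
phi229.2,WCC229,1.0,0.3,1,
phi229.2,WCC232,7.9,1.9,0,
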