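node,n,pct,frontier_estimate,R_t,members
5,4,11,81.0,0.51,CHL COL CRI GRC
6,2,6,75.4,0.03,MEX HUN
7,5,14,78.9,1.95,EST LVA LTU POL TUR
9,4,11,84.5,0.56,JPN BEL IRL PRT
10,3,8,82.6,0.91,CZE ISR SVN
13,2,6,83.9,0.04,LUX CHE
14,10,28,83.3,0.59,CAN AUT DNK DEU ISL ITA NLD NOR ESP NZL
15,6,17,83.6,1.57,USA KOR FIN FRA SWE AUS
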