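sex,age_band,level,median,q1,q3,p95,mode
male,21-40,low,-2.5,-22.5,12.5,57.5,-7.5
male,41-60,low,-7.5,-27.5,12.5,57.5,-12.5
male,61-80,low,-12.5,-32.5,7.5,47.5,-17.5
male,>80,low,-22.5,-37.5,2.5,42.5,-22.5
female,21-40,low,-17.5,-32.5,2.5,37.5,-17.5
female,41-60,low,-17.5,-32.5,2.5,42.5,-17.5
female,61-80,low,-22.5,-42.5,-7.5,27.5,-27.5
female,>80,low,-27.5,-42.5,-7.5,32.5,-27.5
male,21-40,medium,-122.5,-152.5,-92.5,-47.5,-117.5
male,41-60,medium,-107.5,-142.5,-77.5,-32.5,-102.5
male,61-80,medium,-107.5,-142.5,-82.5,-37.5,-102.5
male,>80,medium,-107.5,-142.5,-77.5,-37.5,-97.5
female,21-40,medium,-147.5,-177.5,-117.5,-77.5,-142.5
female,41-60,medium,-117.5,-147.5,-92.5,-52.5,-112.5
female,61-80,medium,-107.5,-132.5,-82.5,-47.5,-102.5
female,>80,medium,-97.5,-122.5,-72.5,-32.5,-87.5
male,21-40,maximum,-422.5,-507.5,-347.5,-237.5,-417.5
male,41-60,maximum,-362.5,-462.5,-287.5,-182.5,-327.5
male,61-80,maximum,-342.5,-452.5,-272.5,-177.5,-307.5
male,>80,maximum,-322.5,-432.5,-247.5,-152.5,-282.5
female,21-40,maximum,-477.5,-567.5,-407.5,-312.5,-442.5
female,41-60,maximum,-382.5,-467.5,-317.5,-212.5,-357.5
female,61-80,maximum,-312.5,-397.5,-252.5,-167.5,-282.5
female,>80,maximum,-267.5,-352.5,-202.5,-122.5,-227.5
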