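id,pic50_observed,binary_observed,ternary_observed,pic50_predicted,binary_predicted,ternary_predicted,ad_warning
68301-99-5,4.26,0,1,5.36,0,1,0
2116443-03-7,4.62,0,1,4.67,0,1,0
2116445-80-6,5.54,0,1,6.22,0,1,0
2116445-76-0,4.00,0,1,5.67,0,1,0
2116445-77-1,4.44,0,1,5.34,0,1,0
2116445-78-2,4.14,0,1,5.33,0,1,0
ext-7,5.35,0,1,5.67,0,1,0
2116445-85-1,4.48,0,1,4.73,0,1,0
70529-18-9,6.40,0,1,5.89,0,1,0
2116445-81-7,5.54,0,1,5.54,0,1,0
2116445-82-8,4.00,0,1,5.80,0,1,0
1056634-68-4,7.24,1,2,7.16,1,3,0
2116443-62-8,6.70,0,1,5.75,0,1,0
2243281-75-4,8.05,1,3,7.80,1,2,0
2243281-77-6,7.70,1,2,7.80,1,2,0
2322365-47-7,8.30,1,3,8.07,0,3,0
81267-65-4,6.02,0,1,5.92,0,1,0
1835675-67-6,8.55,1,3,8.45,0,1,0
2101906-58-3,7.86,1,2,7.76,1,2,1
1903773-70-5,7.70,1,2,6.61,0,1,1
2020003-22-7,6.89,0,1,5.21,0,1,0
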