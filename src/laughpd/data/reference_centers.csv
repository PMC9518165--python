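filter,mel,hfcc,bfcc
1,62.50,31.25,62.50
2,156.25,125.00,156.25
3,218.75,187.50,218.75
4,312.50,281.25,312.50
5,406.25,375.00,375.00
6,531.25,468.75,468.75
7,656.25,593.75,562.50
8,781.25,718.75,656.25
9,937.50,843.75,750.00
10,1093.75,1000.00,875.00
11,1250.00,1156.25,1000.00
12,1437.50,1343.75,1156.25
13,1656.25,1531.25,1281.25
14,1875.00,1781.25,1468.75
15,2125.00,2000.00,1656.25
16,2406.25,2281.25,1843.75
17,2718.75,2562.50,2093.75
18,3062.50,2875.00,2343.75
19,3437.50,3250.00,2656.25
20,3812.50,3625.00,3000.00
21,4281.25,4031.25,3406.25
22,4750.00,4500.00,3875.00
23,5281.25,5031.25,4406.25
24,5875.00,5537.50,5093.75
25,6531.25,6187.50,5937.50
26,7218.75,6875.00,6906.25
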