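subject,hr_sensor,hr_monitor
1,76,78
2,82,81
3,80,83
4,76,75
5,85,86
6,83,85
7,80,80
8,81,82
9,77,79
10,94,93
11,81,83
12,78,78
13,83,85
14,77,78
15,75,75
16,78,79
17,96,96
18,87,89
19,78,81
20,78,79
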