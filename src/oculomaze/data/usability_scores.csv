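Id,Age,Sex,Visual Condition,Score
1,24,Male,No pathology,69
2,24,Male,No pathology,75
3,22,Male,Myopia,75
4,22,Male,No pathology,65
5,22,Male,Left Eye Amblyopia,72.5
6,21,Female,No pathology,72.5
7,27,Male,"Astigmatism, Myopia",77.5
8,22,Male,Right Eye Amblyopia,90
9,18,Female,No pathology,87.5
10,22,Male,No pathology,70
11,19,Male,No pathology,90
12,25,Female,No pathology,82.5
13,21,Female,No pathology,72.5
14,19,Male,No pathology,57.5
15,24,Male,Right Eye Amblyopia,77.5
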