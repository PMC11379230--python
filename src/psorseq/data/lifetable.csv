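age,qx
0.0,0.0003406511529224776
1.0,0.00034472067664659267
2.0,0.00034919713360859195
3.0,0.000354121213114178
4.0,0.0003595376725558097
5.0,0.0003654957440442086
6.0,0.000372049581665701
7.0,0.00037925875342081916
8.0,0.0003871887823012621
9.0,0.00039591174140962693
10.0,0.00040550690851082205
11.0,0.00041606148594242054
12.0,0.00042767139239907603
13.0,0.00044044213375427077
14.0,0.0004544897607934306
15.0,0.0004699419225132617
16.0,0.00048693902450136495
17.0,0.0005056355028503212
18.0,0.0005262012250978332
19.0,0.0005488230308173803
20.0,0.0005737064257312907
21.0,0.0006010774445878164
22.0,0.0006311846995395998
23.0,0.0006643016324119344
24.0,0.0007007289910482273
25.0,0.0007407975519010401
26.0,0.0007848711132010244
27.0,0.0008333497854079441
28.0,0.000886673608247901
29.0,0.0009453265264769417
30.0,0.0010098407596199621
31.0,0.00108080160432944
32.0,0.0011588527117094571
33.0,0.0012447018860014536
34.0,0.0013391274554276356
35.0,0.0014429852707974478
36.0,0.001557216392696903
37.0,0.0016828555337593532
38.0,0.0018210403286705867
39.0,0.001973021511229023
40.0,0.0021401740849943396
41.0,0.00232400958183987
42.0,0.0025261895111011734
43.0,0.0027485401110139973
44.0,0.0029930685237686827
45.0,0.0032619805257844137
46.0,0.0035576999557336286
47.0,0.003882889994397898
48.0,0.004240476462586518
49.0,0.004633673316042919
50.0,0.005066010529421239
51.0,0.005541364574906171
52.0,0.0060639917147339295
53.0,0.006638564340503472
54.0,0.007270210605483274
55.0,0.007964557608738265
56.0,0.00872777840134853
57.0,0.009566643094679694
58.0,0.010488574357834346
59.0,0.011501707595143462
60.0,0.012614956093691787
61.0,0.013838081423999782
62.0,0.01518176936239346
63.0,0.016657711579177725
64.0,0.018278693299973336
65.0,0.020058687095440453
66.0,0.02201295288346372
67.0,0.02415814413339823
68.0,0.026512420139073067
69.0,0.02909556406991398
70.0,0.03192910631078416
71.0,0.03503645235284836
72.0,0.03844301419060947
73.0,0.04217634380367741
74.0,0.04626626684388546
75.0,0.05074501409589394
76.0,0.055647347618055454
77.0,0.06101067768479718
78.0,0.06687516572638408
79.0,0.07328380738113671
80.0,0.0802824885247706
81.0,0.08792000570999603
82.0,0.09624804083021699
83.0,0.10532107801503254
84.0,0.11519624878456469
85.0,0.12593308936279524
86.0,0.13759319182769625
87.0,0.15023972853828615
88.0,0.16393682714495905
89.0,0.17874877162803293
90.0,0.1947390034503128
91.0,0.2119688963564793
92.0,0.23049627899576186
93.0,0.2503736818721627
94.0,0.27164628972907756
95.0,0.2943495880438378
96.0,0.31850670361849487
97.0,0.3441254551303077
98.0,0.3711951507556742
99.0,0.39968319728945634
100.0,0.42953161895682257
101.0,0.46065362427837564
102.0,0.4929304050616026
103.0,0.5262084009205426
104.0,0.5602973122804473
105.0,0.594969189399381
106.0,0.6299589572459057
107.0,0.6649667466816978
108.0,0.6996623800533163
109.0,0.7336922917971826
110.0,0.7666890405142274
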