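id,p,a,d,state_printed,tendency_printed
1,0.75,-1.75,0.5,Gentleness,Negative
2,0.5,-0.5,0.25,Gentleness,Negative
3,0,-0.5,-0.5,Boredom,Negative
4,0.25,-0.25,0.75,Gentleness,Negative
5,-1.25,-1.75,1.25,Boredom,Negative
6,0.75,0.75,0.5,Surprise,Positive
7,-0.25,-1.25,-0.25,Boredom,Negative
8,0.5,1.5,1.5,Surprise,Positive
9,0.5,-2,1,Gentleness,Negative
10,0,-0.75,0.75,Gentleness,Negative
11,-0.25,0.5,0.25,Anxiety,Negative
12,1,0.25,-0.5,Gentleness,Negative
13,-1.5,1,0.5,Resentment,Negative
14,0.5,1,-0.25,Surprise,Positive
15,-0.75,-1,-1,Boredom,Negative
16,-2.25,1,-2,Resentment,Negative
17,-0.5,-0.25,0,Sadness,Negative
18,0.25,-2.5,-2.25,Dependence,Positive
19,-1.75,-1.5,0,Boredom,Negative
20,0,-0.25,0,Anxiety,Negative
21,-0.5,0,-0.25,Sadness,Negative
22,0,0.25,0,Anxiety,Negative
23,0.5,1,-0.5,Fear,Negative
24,0.25,-1,-0.25,Boredom,Negative
25,0.5,-0.75,-1.5,Dependence,Positive
26,0,0,0,Anxiety,Negative
27,0,-0.75,-0.75,Boredom,Negative
28,-1,-1.5,0.5,Boredom,Negative
29,1.25,1.75,0.5,Surprise,Positive
30,0.5,0.5,1.25,Gentleness,Negative
31,1.5,-1,1.25,Relaxation,Positive
32,-0.25,-0.25,0.5,Anxiety,Negative
33,0.57,-0.75,-0.75,Dependence,Positive
34,1.25,-2.5,-2.75,Dependence,Positive
35,-0.75,1.5,2,Contempt,Negative
36,0,1.5,1.75,Joy,Positive
37,0.25,-1.25,-0.5,Boredom,Negative
38,0.25,1.5,1.5,Surprise,Positive
39,0.5,2.25,-1.75,Fear,Negative
40,0.25,2,1,Surprise,Positive
41,0.25,2,1,Surprise,Positive
42,0.5,1.75,2,Joy,Positive
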