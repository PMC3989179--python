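psh_id,parent,n_haplotypes,n_individuals,mean_intra,min_inter,nj_whole,bi_whole,nj_subset,bi_subset,morph_external,morph_internal,published_ssh,applied_name
1,,23,46,0.02,0.08,66,0,0,0,no,yes,(split),
1A,1,20,36,,,99,100,100,99,yes,yes,1A,Arion ater
1B,1,2,8,,,93,63,93,59,no,yes,1B+1C,Arion cf. vulgaris
1C,1,1,2,,,,,,,uncertain,uncertain,1B+1C,Arion cf. vulgaris
2,,9,22,0.00,0.07,100,100,100,100,no,yes,2,Arion rufus
3,,7,8,0.01,0.07,99,100,100,100,no,yes,3,Arion cf. empiricorum
4,,14,26,0.00,0.11,100,100,100,100,yes,yes,4,Arion vulgaris
5,,3,24,0.00,0.10,100,100,100,100,yes,yes,5,Arion flagellus
6,,51,54,0.01,0.17,100,100,100,100,uncertain,yes,6,Arion fuscus
7,,21,47,0.01,0.10,96,100,95,100,yes,yes,7,Arion subfuscus
8,,44,45,0.01,0.14,100,100,100,100,yes,yes,8,Arion subfuscus
9,,2,2,0.02,0.13,100,100,100,100,yes,no,9+10,Arion cf. iratii
10,,2,2,0.03,0.17,100,100,100,100,yes,no,9+10,Arion cf. iratii
11,,48,76,0.04,0.20,100,100,100,90,yes,yes,11,Arion circumscriptus
12,,13,20,0.01,0.20,100,100,100,100,yes,yes,12,Arion fasciatus
13,,8,22,0.01,0.22,100,100,100,100,yes,yes,13,Arion distinctus
14,,4,10,0.00,0.18,100,100,100,100,yes,yes,14,Arion hortensis
15,,7,22,0.01,0.20,100,100,100,100,yes,yes,15,Arion intermedius
16,,1,3,0.01,0.13,100,97,100,98,uncertain,yes,16,Arion occultus
17,,3,12,0.00,0.13,100,100,100,100,yes,yes,17,Arion owenii
18,,4,4,0.00,0.14,100,100,100,100,uncertain,yes,18,Arion cf. fagophilus
19,,1,4,0.00,0.07,,,,,yes,yes,19,Geomalacus maculosus
20,,23,25,0.01,0.06,99,100,99,100,yes,yes,20,Limax cinereoniger
21,,21,24,0.00,0.06,99,100,99,100,yes,yes,21,Limax maximus
22,,10,10,0.03,0.08,99,100,99,100,yes,yes,22,Limax cf. dacampi
23,,9,9,0.00,0.11,100,100,100,100,yes,yes,23,Limacus flavus
24,,14,14,0.01,0.11,100,100,100,100,no,yes,24,Limacus maculatus
25,,26,26,0.01,0.14,100,100,100,100,yes,yes,25,Lehmannia marginata
26,,8,9,0.01,0.08,100,100,100,100,no,yes,26,Ambigolimax valentianus
27,,8,8,0.02,0.08,83,99,97,91,no,yes,27,Ambigolimax nyctelius
28,,5,5,0.01,0.13,100,100,100,100,yes,yes,28,Malacolimax tenellus
29,,8,8,0.02,0.05,99,100,,,no,yes,29,Deroceras agreste
30,,11,14,0.00,0.05,99,84,,,no,yes,30,Deroceras reticulatum
31,,21,26,0.02,0.09,99,100,,,no,yes,31,Deroceras invadens
32,,9,11,0.01,0.08,99,100,,,no,yes,32,Deroceras panormitanum
33,,7,10,0.01,0.05,99,100,,,yes,no,33+34+35+36,Deroceras laeve
34,,4,5,0.00,0.06,99,100,,,yes,no,33+34+35+36,Deroceras laeve
35,,4,4,0.01,0.05,99,100,,,yes,no,33+34+35+36,Deroceras laeve
36,,12,20,0.02,0.05,57,0,,,yes,no,33+34+35+36,Deroceras laeve
37,,4,4,0.01,0.11,100,100,,,yes,yes,37,Milax gagates
38,,10,11,0.00,0.10,100,91,,,yes,no,38,Tandonia budapestensis
39,,3,3,0.04,0.11,99,97,,,yes,no,39,Tandonia cf. cristata
40,,10,10,0.03,0.10,98,100,,,yes,yes,40,Tandonia sowerbyi
41,,1,2,0.00,0.19,,,,,yes,yes,41,Tandonia rustica
42,,5,7,0.01,0.22,100,100,,,yes,yes,42,Testacella haliotidea
43,,5,8,0.00,0.22,100,100,,,yes,yes,43,Testacella maugei
44,,2,2,0.00,0.20,100,100,,,yes,yes,44,Testacella scutulum
45,,5,5,0.00,0.20,100,100,,,yes,yes,45,Testacella cf. scutulum
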