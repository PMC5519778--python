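# units: length_cm,radius_cm,thickness_cm in cm; E_Pa in Pa; R1,R0 in Pa.s.m^-5; Cp in m^5.Pa^-1; parent=0 marks the root
id,name,parent,length_cm,radius_cm,thickness_cm,elastic_class,E_Pa,R1,R0,Cp
1,ascending aorta,0,4.0,1.455,0.163,large,400000.0,,,
2,aortic arch A,1,2.0,1.12,0.126,large,400000.0,,,
3,brachiocephalic,1,3.4,0.62,0.08,large,400000.0,,,
4,R. subclavian A,3,3.4,0.423,0.067,large,400000.0,,,
5,R. common carotid,3,17.7,0.37,0.063,large,400000.0,,,
6,R. vertebral,4,14.8,0.186,0.045,medium,800000.0,927467433.1420149,5952846497.971884,2.277599815638769e-10
7,R. subclavian B (brachial),4,42.2,0.32,0.067,large,400000.0,,,
8,R. radial,7,23.5,0.158,0.043,peripheral,1600000.0,1927885694.4596756,9296842314.255623,1.396078526702351e-10
9,R. ulnar A,7,6.7,0.215,0.046,peripheral,1600000.0,,,
10,aortic arch B,2,3.9,1.07,0.115,large,400000.0,,,
11,L. common carotid,2,20.8,0.37,0.063,large,400000.0,,,
12,L. subclavian A,10,3.4,0.423,0.066,large,400000.0,,,
13,thoracic aorta A,10,5.2,0.999,0.11,large,400000.0,,,
14,L. subclavian B (brachial),12,42.2,0.32,0.067,large,400000.0,,,
15,L. radial,14,23.5,0.158,0.043,peripheral,1600000.0,1927885694.4596756,9296842314.255623,1.396078526702351e-10
16,L. ulnar A,14,6.7,0.215,0.046,peripheral,1600000.0,,,
17,intercostals,13,8.0,0.175,0.049,medium,800000.0,1127139554.8553143,7133866510.499669,1.8969362347718465e-10
18,thoracic aorta B,13,10.4,0.66,0.1,large,400000.0,,,
19,abdominal aorta A,18,5.3,0.61,0.09,large,400000.0,,,
20,celiac A,18,1.0,0.39,0.064,medium,800000.0,,,
21,celiac B,20,1.0,0.2,0.064,medium,800000.0,,,
22,hepatic,20,6.6,0.22,0.049,medium,800000.0,636086400.47831,3521861512.886816,3.768830699074169e-10
23,gastric,21,7.1,0.18,0.045,medium,800000.0,1006699300.013428,6584835230.424134,2.0642205707175576e-10
24,splenic,21,6.3,0.275,0.054,medium,800000.0,382243331.72761804,1746625999.9153256,7.360997459129239e-10
25,superior mesenteric,19,5.9,0.435,0.069,medium,800000.0,137301782.51577103,400570687.39263475,2.913441869168432e-09
26,abdominal aorta B,19,1.0,0.6,0.08,large,400000.0,,,
27,L. renal,26,3.2,0.26,0.053,medium,800000.0,435691750.9096341,2083301727.7835755,6.22097749501574e-10
28,abdominal aorta C,26,1.0,0.59,0.08,large,400000.0,,,
29,R. renal,28,3.2,0.26,0.053,medium,800000.0,435691750.9096341,2083301727.7835755,6.22097749501574e-10
30,abdominal aorta D,28,10.6,0.564,0.075,large,400000.0,,,
31,inferior mesenteric,30,5.0,0.16,0.043,medium,800000.0,1321018937.9752545,9488021438.370413,1.449768082589012e-10
32,abdominal aorta E,30,1.0,0.52,0.065,large,400000.0,,,
33,R. common iliac,32,5.8,0.39,0.06,large,400000.0,,,
34,L. common iliac,32,5.8,0.39,0.06,large,400000.0,,,
35,L. external iliac,34,14.4,0.32,0.053,medium,800000.0,,,
36,L. internal iliac,34,5.0,0.2,0.04,peripheral,1600000.0,1031441917.0484332,4502786755.640548,2.8315782863066643e-10
37,L. femoral,35,44.3,0.225,0.05,medium,800000.0,,,
38,L. deep femoral,35,12.6,0.221,0.047,peripheral,1600000.0,871079945.1250077,3230680248.1470623,3.820457804126541e-10
39,L. posterior tibial,37,32.1,0.194,0.045,peripheral,1600000.0,1180569889.7097077,4883188622.582188,2.584305049298362e-10
40,L. anterior tibial,37,34.3,0.13,0.039,peripheral,1600000.0,2989948397.735804,17161999431.809874,7.776221868769675e-11
41,R. external iliac,33,14.4,0.32,0.053,medium,800000.0,,,
42,R. internal iliac,33,5.0,0.2,0.04,peripheral,1600000.0,1031441917.0484332,4502786755.640548,2.8315782863066643e-10
43,R. femoral,41,44.3,0.225,0.05,medium,800000.0,,,
44,R. deep femoral,41,12.6,0.221,0.047,peripheral,1600000.0,871079945.1250077,3230680248.1470623,3.820457804126541e-10
45,R. posterior tibial,43,32.1,0.194,0.045,peripheral,1600000.0,1180569889.7097077,4883188622.582188,2.584305049298362e-10
46,R. anterior tibial,43,34.3,0.13,0.039,peripheral,1600000.0,2989948397.735804,17161999431.809874,7.776221868769675e-11
47,R. ulnar B,9,17.1,0.203,0.046,peripheral,1600000.0,1065684358.239918,4226792568.7013903,2.9609201811104375e-10
48,R. interosseous,9,7.9,0.091,0.028,peripheral,1600000.0,6179670301.909758,52572364186.56161,2.6672441009879985e-11
49,L. ulnar B,16,17.1,0.203,0.046,peripheral,1600000.0,1065684358.239918,4226792568.7013903,2.9609201811104375e-10
50,L. interosseous,16,7.9,0.091,0.028,peripheral,1600000.0,6179670301.909758,52572364186.56161,2.6672441009879985e-11
51,R. internal carotid,5,17.6,0.2,0.045,peripheral,1600000.0,1094009360.9174993,4440219311.7714815,2.8315782863066643e-10
52,R. external carotid,5,17.7,0.15,0.042,peripheral,1600000.0,2169632950.36151,10948538718.234598,1.1945720895356234e-10
53,L. internal carotid,11,17.6,0.2,0.045,peripheral,1600000.0,1094009360.9174993,4440219311.7714815,2.8315782863066643e-10
54,L. external carotid,11,17.7,0.15,0.042,peripheral,1600000.0,2169632950.36151,10948538718.234598,1.1945720895356234e-10
55,L. vertebral,12,14.8,0.186,0.045,medium,800000.0,927467433.1420149,5952846497.971884,2.277599815638769e-10
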