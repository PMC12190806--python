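site,season,total,g1,g2,g3,g4,g5,g6,g7,g8,g9,g10,g11,g12,g13,g14,g15,g16,g17,g18,g19,g20,g21,g22,g23,g24,g25,g26,g27,g28,g29
Negratin,spring,2036,64.6,0.0,2.1,1.8,8.3,0.4,0.0,0.1,0.0,1.4,0.9,0.0,6.6,0.0,0.0,0.0,0.1,0.0,0.0,1.5,0.0,0.8,0.0,3.2,0.7,7.2,0.0,0.0,0.0
Malaha,spring,678,40.7,16.7,1.8,2.4,1.0,0.0,2.9,0.0,0.0,0.0,0.0,0.0,11.7,0.4,0.0,0.4,1.9,2.8,0.7,6.3,0.6,4.9,0.1,1.8,0.9,1.9,0.0,0.0,0.0
Baza,spring,319,70.5,0.0,9.1,0.9,8.5,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,3.4,0.0,0.0,2.5,0.0,0.0,0.0,0.3,0.0,0.0,0.0,0.0,4.7
Quesada,spring,194,97.9,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Tabernas,spring,240,66.7,0.0,1.3,0.0,9.6,0.0,0.0,0.0,0.0,0.0,0.0,0.0,20.8,0.0,0.0,0.0,0.8,0.8,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Olula,spring,1318,64.6,0.0,3.6,1.4,4.1,0.0,1.5,0.0,0.0,0.0,0.0,0.0,9.8,0.2,0.0,0.2,2.3,1.6,0.4,3.9,0.3,2.5,0.1,1.0,0.6,1.0,0.0,0.0,1.1
Negratin,summer,968,16.2,0.0,13.7,3.6,36.0,6.8,0.0,0.0,0.2,0.3,6.4,0.2,0.0,0.4,0.2,0.1,3.3,0.5,0.2,2.8,0.2,0.0,0.0,1.8,3.9,1.1,0.1,1.4,0.4
Malaha,summer,288,1.7,0.0,1.0,0.0,44.1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7.6,0.0,0.0,2.4,12.8,0.0,0.0,22.9,0.0,0.0,2.4,0.0,2.8,0.7,0.0,0.0,1.4
Baza,summer,0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Quesada,summer,140,0.0,0.0,0.0,0.0,57.1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,28.5,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,7.1,0.0,0.0,7.1
Tabernas,summer,60,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,16.7,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,66.7,0.0,0.0,0.0,0.0,16.7
Olula,summer,488,1.0,0.0,0.6,0.0,42.4,0.0,0.0,0.0,0.0,0.0,0.0,0.0,14.8,0.0,0.0,1.4,7.6,0.0,0.0,13.5,0.0,0.0,1.4,8.2,1.6,2.5,0.0,0.0,4.9
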