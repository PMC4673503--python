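enzyme,group,substrate,kcat,kcat_sd,km_mM,km_sd,eff,eff_sd
GEO179,discovered,C3,,,,,0.9,0.02
GEO179,discovered,C5,0.47,0.03,4.6,0.6,100,15
GEO179,discovered,C8,0.32,0.01,0.27,0.03,1200,130
GEO179,discovered,isoC5,0.39,0.01,9.4,0.2,41,1.2
GEO195,discovered,C3,,,,,2.4,0.1
GEO195,discovered,C5,0.49,0.01,2.5,0.2,200,14
GEO195,discovered,C8,0.56,0.02,0.4,0.04,1400,160
GEO195,discovered,isoC5,0.072,0.001,9.1,0.3,8,0.3
GEO175,discovered,C3,,,,,0.51,0.02
GEO175,discovered,C5,0.97,0.04,20,1.3,48,3.7
GEO175,discovered,C8,10.1,0.6,0.58,0.09,17000,2700
GEO175,discovered,isoC5,,,,,3.3,0.2
GEO175_L376T_T240S,designed,C3,,,,,0.27,0.02
GEO175_L376T_T240S,designed,C5,0.28,0.04,10,2,30,7.2
GEO175_L376T_T240S,designed,C8,3.4,0.2,3.1,0.4,1100,160
GEO175_L376T_T240S,designed,isoC5,,,,,1.6,0.1
1OVM,naive,C3,0.2,0.01,7.5,0.1,32,0.5
1OVM,naive,C5,1,0.1,0.5,0.1,2100,420
1OVM,naive,C8,1.7,0.1,0.021,0.001,80000,4300
1OVM,naive,isoC5,7.8,0.4,6.1,0.6,1300,130
2VBI,naive,C3,25,2.6,4.3,1.0,5700,1400
2VBI,naive,C5,,,,,52,1.8
2VBI,naive,C8,0.051,0.01,3.6,0.2,14,0.8
2VBI,naive,isoC5,0.025,0.001,14,0.5,1.8,0.1
3FZN,naive,C3,,,,,5.4,0.1
3FZN,naive,C5,4.7,0.1,2.7,0.2,1700,110
3FZN,naive,C8,1.3,0.1,3.8,0.3,350,30
3FZN,naive,isoC5,0.52,0.02,4.9,0.3,110,10
1ZPD,naive,C3,46.7,1.4,5.7,0.3,8200,545
1ZPD,naive,C5,0.95,0.02,7.1,0.3,140,5.6
1ZPD,naive,C8,0.021,0.001,1.2,0.1,19,2
1ZPD,naive,isoC5,,,,,0.33,0.01
1OZF,naive,C3,,,,,,
1OZF,naive,C5,,,,,0.53,0.04
1OZF,naive,C8,,,,,,
1OZF,naive,isoC5,0.03,0.001,1.8,0.1,17,0.9
KIVD,native,C3,,,,,42,0.6
KIVD,native,C5,14.3,0.2,1.5,0.1,9500,470
KIVD,native,C8,7,0.3,0.21,0.04,32000,5500
KIVD,native,isoC5,61,2.1,4.5,0.3,14000,1100
KIVD_VLV,designed,C3,,,,,0.71,0.07
KIVD_VLV,designed,C5,0.013,0.001,10,1,1.3,0.2
KIVD_VLV,designed,C8,0.5,0.03,0.18,0.05,2800,860
KIVD_VLV,designed,isoC5,,,,,0.24,0.02
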