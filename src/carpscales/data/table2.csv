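no,label,alias,cross_type,location,male_origin,female_origin,male_id,female_id,total_n,expected_scaled,expected_linear,expected_scattered,expected_nude,expected_lethal,obs_scaled,obs_linear,obs_irregular,obs_mirror,obs_nude,inconsistent_with_model
1,1nu.nu,,nude x nude,SIN,Hun,Koi,CcB01,CcB02,161,,,25%,50%,25%,0.0,0.0,15.5,25.5,59.0,false
2,2nu.nu,,nude x nude,SIN,Koi,Koi,CcB03,CcB02,92,,,25%,50%,25%,1.1,0.0,15.2,25.0,58.7,false
3,26nu.nu,,nude x nude,HUN,Hun,Hun,CcB04,CcB05,208,,,25%,50%,25%,0.0,0.0,0.0,13.0,87.0,false
4,35nu.nu,,nude x nude,SIN,Hun,Koi,CcB01,CcB06,218,,,25%,50%,25%,0.0,0.0,53.2,2.3,44.5,false
5,38nu.nu,,nude x nude,SIN,Hun,F1hyb,CcB01,CcB07,110,,,25%,50%,25%,0.0,0.0,55.5,20.0,24.5,false
6,41nu.nu,,nude x nude,SIN,Hun,Koi,CcB01,CcB08,253,,,25%,50%,25%,0.0,0.0,35.6,26.1,38.3,false
7,21nu.mi,21mi.nu,nude x mirror,HUN,Hun,Hun,CcB04,CcB09,186,,,50%,50%,,0.0,1.1,0.0,96.2,2.7,false
8,25mi.nu,25nu.mi,nude x mirror,HUN,Hun,Hun,CcB10,CcB05,233,,,50%,50%,,0.0,0.0,0.0,100.0,0.0,false
9,32nu.mi,,nude x mirror,SIN,Hun,F1hyb,CcB01,CcB11,268,,,50%,50%,,0.0,0.0,57.5,18.2,24.3,false
10,36mi.nu,,nude x mirror,SIN,F1hyb,Koi,CcB12,CcB06,177,,,50%,50%,,0.0,0.0,73.4,1.7,24.9,false
11,34nu.ir,,nude x irregular,SIN,Hun,F1hyb,CcB01,CcB13,414,,,50%,50%,,0.0,0.0,76.1,18.4,5.5,false
12,39ir.nu,,nude x irregular,SIN,F1hyb,F1hyb,CcB14,CcB07,54,,,50%,50%,,0.0,0.0,44.5,22.2,33.3,false
13,40nu.ir,,nude x irregular,SIN,Hun,F1hyb,CcB01,CcB15,114,,,50%,50%,,0.0,0.0,52.6,34.2,13.2,false
14,33mi.ir,,mirror x irregular,SIN,F1hyb,F1hyb,CcB12,CcB13,304,,,100%,,,0.0,0.0,86.2,13.2,0.6,false
15,37mi.ir,,mirror x irregular,SIN,F1hyb,F1hyb,CcB12,CcB14,236,,,100%,,,0.0,0.0,64.8,35.2,0.0,false
16,22nu.li,22li.nu,linear x nude,HUN,Hun,Hun,CcB04,CcB15,118,12.5 or 25%,25 or 50%,0 or 12.5%,0 or 25%,25%,0.0,2.5,0.0,88.2,9.3,false
17,27li.nu,27nu.li,linear x nude,HUN,Hun,Hun,CcB16,CcB05,289,12.5 or 25%,25 or 50%,0 or 12.5%,0 or 25%,25%,0.0,1.0,0.0,98.6,0.3,false
18,9mi.li,,linear x mirror,HUN,Hun,Hun,CcB17,CcB18,52,25 or 25%,25 or 50%,25 or 50%,0 or 25%,,0.0,67.3,1.9,23.1,7.7,true
19,23mi.li,23li.mi,linear x mirror,HUN,Hun,Hun,CcB10,CcB15,204,25 or 50%,25 or 50%,25 or 50%,0 or 25%,,0.5,32.8,0.0,66.7,0.0,true
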