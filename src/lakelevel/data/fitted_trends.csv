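lake,dic,delta_dic_null,beta1_e4_mean,beta1_e4_lo,beta1_e4_hi,p1_mean,p1_lo,p1_hi,p2_mean,p2_lo,p2_hi,p3_mean,p3_lo,p3_hi
Akibbon,-34.2,21.8,0.1,-1.9,2.2,12.04,11.92,12.15,84.6,28.61,130.42,202.98,145.99,256.8
Anure,-167.4,19.3,-0.1,-0.7,0.6,11.99,11.95,12.04,,,,,,
Bawn,-71.6,64.6,-1.1,-2,-0.3,11.97,11.94,12,223.53,30.74,416.57,,,
Cullin,193.8,71.5,-0.3,-2.1,1.4,12.01,11.96,12.05,154.32,32.59,299.34,,,
Cutra,-55.1,57.6,-0.2,-1.2,0.7,12,11.96,12.03,75.6,27.77,128.67,306.89,153.79,423.09
Derryclare,-237.7,45.3,-1.4,-2.4,0.4,12,11.95,12.04,,,,,,
Derrygooney,-267.4,114.5,-1.9,-3.2,-0.6,11.98,11.95,12,208.62,49.52,379.35,,,
Dromore,-156,113.5,-0.3,-2.1,1.2,11.97,11.94,11.99,350.76,109.99,433.07,,,
Egish,-383.3,84.8,-1.2,-2,-0.4,11.97,11.94,12.01,,,,,,
Emy,9.8,72.1,3.1,0.9,5,11.97,11.93,12.01,235.84,65.28,358.14,,,
Eske,-537.3,37.3,-0.1,-1.1,1,12.01,11.97,12.05,77.54,27.78,126.37,369.61,297.79,413.25
Fad,-517.9,7.7,-0.8,-1.6,0.1,12,11.95,12.05,,,,,,
Feeagh,-510.2,67.1,-1.6,-2.4,-0.8,11.98,11.95,12.01,,,,,,
Fern,22.2,73.6,-0.3,-2.6,2.1,12.03,11.98,12.08,,,,,,
Gartan,-188.6,41.5,-1.7,-3.7,0.2,12.03,11.96,12.1,130.63,45.83,272.17,,,
Garty,-193.2,25.3,4,1.4,6.9,12.02,11.95,12.09,234.41,187.45,273.84,,,
Gill,-14,13.3,-0.3,-1,0.3,11.98,11.94,12.02,,,,,,
Gleincmurrin,-125.7,62,-0.1,-1.4,1.2,11.99,11.95,12.03,343.52,74.89,422.27,,,
Gowna,39.8,172.6,-1.8,-2.9,-0.7,11.97,11.95,11.99,,,,,,
Inchiquin,-94.4,111.5,-0.5,-1.8,0.7,11.99,11.96,12.02,294.51,109.14,418.84,,,
Islandeady,-1.9,47.8,-4.6,-8.3,-0.7,12.03,11.96,12.09,74.05,44.61,112.28,194.57,146.95,234.25
Lickeen,-141.4,24.6,-3.4,-5.3,-1.7,12.01,11.95,12.07,272.42,219.52,327.87,,,
Muckno,95.8,52.6,-2.6,-3.8,-1.1,11.99,11.94,12.04,253.45,43.44,426.77,,,
Nadregeel,-160.5,78.8,-1.1,-2.5,0.5,12.01,11.97,12.05,218.52,33.95,345.55,,,
Oughter,527.3,168.2,-1.5,-3.1,0.1,11.98,11.96,12,,,,,,
Sillan,-192.3,125,-0.3,-1.4,0.8,12,11.97,12.03,,,,,,
Skeagh,-234.4,15,-0.3,-1,0.4,11.99,11.95,12.03,254.66,39.11,435.28,,,
White,54.7,119.1,-1,-3.2,0.9,11.97,11.94,12,278.2,53.83,402.14,,,
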