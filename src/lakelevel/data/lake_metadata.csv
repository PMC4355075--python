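lake,abbr,latitude,longitude,county,start,end,pct_missing,abstraction_hm3_yr,surface_area_ha,mean_depth_m
Akibbon,Ak,55.013,-7.892,Donegal,1975-11,1997-05,0,0,44.5,
Anure,An,55.007,-8.276,Donegal,1975-11,2012-01,0.2,1.67,132.6,4.5
Bawn,Ba,54.047,-6.91,Monaghan,1976-10,2012-02,1.9,0.95,30.4,
Cullin,Cu,53.966,-9.141,Mayo,1983-09,2009-01,4.3,0,1019.3,5
Cutra,Ct,53.028,-8.772,Galway,1976-09,2012-03,4.9,0,382,4
Derryclare,De,53.464,-9.803,Galway,1979-04,2012-03,1.3,0,222.5,6.9
Derrygooney,Dr,54.042,-6.942,Monaghan,1976-10,2009-12,2.8,0,23.2,
Dromore,Dr,54.082,-7.087,Monaghan,1975-11,2012-02,6.9,0,60.5,2.9
Egish,Eg,54.058,-6.774,Monaghan,1975-03,2009-03,2.4,0,111.4,3.3
Emy,Em,54.347,-6.937,Monaghan,1981-10,2012-01,3,0.3,52.4,
Eske,Es,54.687,-8.052,Donegal,1977-09,2012-03,0,1.09,385.2,7.3
Fad,Fa,55.234,-7.376,Donegal,1978-09,2012-03,11.4,1.4,40.2,5.8
Feeagh,Fe,53.925,-9.572,Mayo,1976-03,2012-02,2.5,0,393.1,14.5
Fern,Fr,55.054,-7.727,Donegal,1976-09,1999-07,0.4,0,180.3,1
Gartan,Ga,55.003,-7.906,Donegal,1975-11,1999-07,0,0.1,202.8,4
Garty,Gr,53.925,-7.583,Cavan,1977-10,2000-09,1.8,1.02,82.2,6.7
Gill,Gi,54.249,-8.439,Sligo,1975-03,2012-02,0.5,4.9,1375.3,5
Gleincmurrin,Gl,53.308,-9.498,Galway,1976-07,2011-11,2.1,0,162.3,3.8
Gowna,Go,53.866,-7.544,Cavan,1976-06,2012-02,3.7,0.09,1146.7,3.7
Inchiquin,In,52.951,-9.083,Clare,1976-11,2011-12,2.6,0.17,107.3,10.1
Islandeady,Is,53.838,-9.372,Mayo,1976-10,1996-05,0.8,0,138.5,3.2
Lickeen,Li,52.963,-9.245,Clare,1976-01,2003-08,1.5,1.68,83.9,3.9
Muckno,Mu,54.1,-6.682,Monaghan,1976-02,2012-01,4.2,0.13,354.3,5.4
Nadregeel,Na,53.883,-7.162,Cavan,1976-11,2005-12,8,1.02,84.3,2.4
Oughter,Ou,54.038,-7.433,Cavan,1977-10,2012-02,0.2,0,658.2,2.6
Sillan,Si,54.007,-6.947,Cavan,1974-11,2006-01,0.5,0,161.5,4.8
Skeagh,Sk,53.951,-7.007,Cavan,1975-06,2012-02,0.9,1.21,61,2.2
White,Wh,54.114,-6.972,Monaghan,1976-04,2009-12,1.5,0.26,53.6,1
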