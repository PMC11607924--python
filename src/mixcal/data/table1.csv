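sample_id,set,PIO_ugmL,ALG_ugmL,GLM_ugmL
St1,St,27.00,22.50,4.40
M1,M,30.00,25.00,4.00
M2,M,30.00,20.00,3.20
M3,M,24.00,20.00,4.80
M4,M,24.00,30.00,3.60
M5,M,36.00,22.50,4.80
St2,St,27.00,22.50,4.40
M6,M,27.00,30.00,4.00
M7,M,36.00,25.00,3.60
M8,M,30.00,22.50,3.60
M9,M,27.00,22.50,4.40
M10,M,27.00,27.50,4.80
St3,St,27.00,22.50,4.40
M11,M,33.00,30.00,4.40
M12,M,36.00,27.50,4.00
M13,M,33.00,25.00,4.80
M14,M,30.00,30.00,4.80
M15,M,36.00,30.00,3.20
St4,St,27.00,22.50,4.40
M16,M,36.00,20.00,4.40
M17,M,24.00,27.50,3.20
M18,M,33.00,20.00,4.00
M19,M,24.00,25.00,4.40
M20,M,30.00,27.50,4.40
St5,St,27.00,22.50,4.40
M21,M,33.00,27.50,3.60
M22,M,33.00,22.50,3.20
M23,M,27.00,20.00,3.60
M24,M,24.00,22.50,4.00
M25,M,27.00,25.00,3.20
St6,St,27.00,22.50,4.40
T1,T,25.00,26.50,3.67
T2,T,31.00,26.10,3.27
T3,T,24.00,20.60,3.65
T4,T,30.00,27.86,3.47
T5,T,32.50,21.98,3.65
T6,T,27.00,26.10,3.27
T7,T,25.50,23.35,3.06
T8,T,27.00,29.23,3.06
T9,T,32.50,24.73,3.86
T10,T,25.50,27.86,4.67
T11,T,27.00,21.98,3.27
T12,T,33.50,26.10,4.65
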