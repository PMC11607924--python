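dosage_form,mixture,model,analyte,added_ugmL,recovery_pct
Prandglim,1,PLS,PIO,27.00,100.72
Prandglim,2,PLS,PIO,33.00,104.48
Prandglim,3,PLS,PIO,36.00,106.15
Prandglim,1,PLS,ALG,22.50,102.20
Prandglim,2,PLS,ALG,27.50,105.70
Prandglim,3,PLS,ALG,30.00,100.46
Prandglim,1,ANN,PIO,27.00,95.15
Prandglim,2,ANN,PIO,33.00,99.04
Prandglim,3,ANN,PIO,36.00,97.46
Prandglim,1,SVR,PIO,27.00,100.15
Prandglim,2,SVR,PIO,33.00,100.35
Prandglim,3,SVR,PIO,36.00,98.09
Prandglim,1,SVR,ALG,22.50,104.84
Prandglim,2,SVR,ALG,27.50,105.17
Prandglim,3,SVR,ALG,30.00,104.55
Prandglim,1,XGB,PIO,27.00,99.96
Prandglim,2,XGB,PIO,33.00,102.09
Prandglim,3,XGB,PIO,36.00,100.00
Prandglim,1,XGB,ALG,22.50,103.91
Prandglim,2,XGB,ALG,27.50,104.99
Prandglim,3,XGB,ALG,30.00,99.35
Piompride,1,PLS,PIO,30.00,102.25
Piompride,2,PLS,PIO,33.00,100.87
Piompride,3,PLS,PIO,36.00,95.29
Piompride,1,ANN,PIO,30.00,100.29
Piompride,2,ANN,PIO,33.00,99.72
Piompride,3,ANN,PIO,36.00,93.29
Piompride,1,SVR,PIO,30.00,101.30
Piompride,2,SVR,PIO,33.00,99.57
Piompride,3,SVR,PIO,36.00,92.89
Piompride,1,XGB,PIO,30.00,101.92
Piompride,2,XGB,PIO,33.00,100.30
Piompride,3,XGB,PIO,36.00,93.24
Piompride,1,XGB,GLM,4.00,100.33
Piompride,2,XGB,GLM,4.40,98.68
Piompride,3,XGB,GLM,4.60,97.36
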