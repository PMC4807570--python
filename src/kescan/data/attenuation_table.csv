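element,energy_keV,mu_over_rho_cm2_g,edge_flag
H,10.0,0.3854,
H,15.0,0.3764,
H,20.0,0.3695,
H,25.0,0.3626,
H,30.0,0.3570,
C,10.0,2.373,
C,15.0,0.8071,
C,20.0,0.4420,
C,25.0,0.3274,
C,30.0,0.2562,
N,10.0,3.879,
N,15.0,1.236,
N,20.0,0.6178,
N,25.0,0.4203,
N,30.0,0.3066,
O,10.0,5.952,
O,15.0,1.836,
O,20.0,0.8651,
O,25.0,0.5485,
O,30.0,0.3779,
Ca,10.0,93.40,
Ca,15.0,30.30,
Ca,20.0,12.55,
Ca,25.0,6.77,
Ca,30.0,4.08,
Fe,10.0,170.6,
Fe,15.0,57.08,
Fe,20.0,25.68,
Fe,25.0,13.68,
Fe,30.0,8.176,
Zn,10.0,108.6,
Zn,15.0,36.07,
Zn,20.0,16.62,
Zn,25.0,8.94,
Zn,30.0,5.38,
Y,10.0,90.80,
Y,15.0,29.37,
Y,17.037,20.68,below_edge
Y,17.040,129.8,above_edge
Y,20.0,82.80,
Y,25.0,44.40,
Y,30.0,27.00,
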