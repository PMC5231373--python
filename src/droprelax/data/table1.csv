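magnitude,droplet,process,a,b,lambda_c,beta,r2
area,1,elongation,176.1,68.13,13.22,1.31,0.90
area,2,elongation,319.1,320.1,16.22,2.24,1.00
area,3,elongation,112.5,138.8,7.980,1.13,0.98
area,4,elongation,285.2,203.7,14.59,2.02,0.96
area,5,elongation,322.1,333.7,13.12,1.29,0.99
ar,1,elongation,1.15,3.126,9.873,1.04,0.99
ar,2,elongation,1.02,4.081,11.02,0.82,0.98
ar,3,elongation,1.06,2.197,6.325,0.89,0.98
ar,4,elongation,1.20,3.068,17.34,2.30,0.98
ar,5,elongation,1.09,4.145,13.23,1.22,0.99
major,1,elongation,16.00,20.51,11.43,1.09,0.97
major,2,elongation,20.64,43.25,13.85,1.14,0.99
major,3,elongation,12.35,19.83,7.150,1.00,0.99
major,4,elongation,20.83,30.66,16.87,2.16,0.99
major,5,elongation,21.20,44.95,13.66,1.25,1.00
area,1,recovery,281.9,-114.8,10.16,1.22,0.97
area,2,recovery,641.5,-330.2,13.15,1.68,1.00
area,3,recovery,232.2,-121.8,4.560,2.04,0.94
area,4,recovery,492.7,-195.7,12.49,4.95,0.98
area,5,recovery,675.3,-428.4,9.520,1.38,0.98
ar,1,recovery,3.87,-2.837,13.930,1.69,0.89
ar,2,recovery,4.49,-3.417,14.121,1.91,0.99
ar,3,recovery,3.16,-2.072,14.217,4.10,0.98
ar,4,recovery,4.38,-3.244,13.515,1.94,0.99
ar,5,recovery,5.44,-4.528,22.019,0.984,1.00
major,1,recovery,37.21,-22.21,12.62,1.58,1.00
major,2,recovery,60.49,-39.65,13.68,1.86,0.99
major,3,recovery,30.59,-17.70,11.61,12.0,1.00
major,4,recovery,52.13,-30.20,12.75,2.87,1.00
major,5,recovery,67.13,-50.19,14.84,1.06,1.00
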