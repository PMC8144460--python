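name,family,location,spread,lower,upper,units
BW,lognormal,4.36,0.313,3.747,4.973,kg
GFRC,lognormal,3.14,0.294,2.564,3.716,L/h/kg kidney
Protein,normal,2e-6,6e-7,8.24e-7,3.18e-6,mg protein/proximal tubule cell
VLC,normal,0.026,0.0078,0.0107,0.0413,L/kg BW
VfilC,normal,0.0004,0.00012,0.000165,0.000635,L/kg BW
VKC,normal,0.004,0.0008,0.0024,0.0056,L/kg BW
VplasC,normal,0.0428,0.009,0.025,0.061,L/kg BW
VPTCC,uniform,,,7.7e-5,1.9e-4,L/g kidney
QCC,normal,12.5,2,8.5,16,L/h/kg BW^0.75
QLC,normal,0.25,0.05,0.15,0.35,fraction CO
QKC,normal,0.175,0.03,0.12,0.24,fraction CO
Htc,normal,0.44,0.09,0.26,0.62,unitless
PL,lognormal,0.01,0.198,-0.378,0.398,unitless
PK,normal,1.17,0.2,0.77,1.6,unitless
PR,normal,0.11,0.02,0.07,0.15,unitless
Vmax_apical_invitro,lognormal,10.48,0.325,9.843,11.117,pmol/mg protein/min
KM_apical,lognormal,11.25,0.161,10.929,11.561,ug/L
RAFapi,lognormal,-7.31,0.294,-7.886,-6.734,unitless
KbileC,lognormal,-9.25,0.294,-9.826,-8.674,/h/kg^-0.25
KurineC,lognormal,-2.81,0.294,-3.386,-2.243,/h/kg^-0.25
Free,lognormal,-3.96,0.294,-4.536,-3.384,unitless
Vmax_baso_invitro,normal,439.2,90,259.2,619.2,pmol/mg protein/min
KM_baso,normal,20100.0,4000,12100,28100,ug/L
RAFbaso,normal,1.0,0.2,0.6,1.4,unitless
Kdif,normal,0.001,0.0002,0.0006,0.0014,L/h
Kabsc,normal,2.12,0.04,1.3,2.9,1/(h*BW^-0.25)
Kunabsc,normal,7.06e-5,1.0e-5,5.1e-5,9.1e-5,1/(h*BW^-0.25)
GEC,normal,3.5,0.7,2.1,4.9,1/(h*BW^-0.25)
K0C,normal,1.0,0.2,0.6,1.4,1/(h*BW^-0.25)
Keffluxc,normal,0.1,0.02,0.06,0.14,1/(h*BW^-0.25)
ExposedDW,lognormal,1.22,0.294,0.648,1.800,ug/L
DWtotal,lognormal,0.181,0.503,-0.805,1.167,L/day
Ingest_past,lognormal,-3.69,0.294,-5.570,-3.270,ug/h
Ingest_current,lognormal,-4.65,0.294,-5.226,-4.074,ug/h
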