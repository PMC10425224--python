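# Packaged registry of fitted duration-response curves for waterlogging
# stress response indices (WSRI) of 26 cotton growth, root, pigment and
# gas-exchange/fluorescence parameters.
# Coefficients a, b, c are AS PRINTED; linear rows are disambiguated to
# (slope, intercept) at load time by the nearest-to-1-intercept rule.
# trend: narrative direction of the WSRI with waterlogging duration
# (dec = decreases, inc = increases), used to flag direction conflicts.
# version: published-2023
parameter_code,description,family,a,b,c,r_squared,trend
PH,Plant height,quadratic,0.0032,-0.087,1.056,0.96,dec
SD,Stem diameter,quadratic,0.0039,-0.098,1.101,0.98,dec
LN,Mainstem leaf number,quadratic,0.0017,-0.054,1.023,0.97,dec
LA,Leaf area,exp_decay,0.9770,-0.158,,0.92,dec
DWL,Dry weight of leaves,exp_decay,0.9188,-0.118,,0.85,dec
DWS,Dry weight of stems,exp_decay,0.9157,-0.118,,0.84,dec
DWSh,Dry weight of shoot,exp_decay,0.9410,-0.121,,0.87,dec
DWT,Dry weight of whole plant,exp_decay,0.9611,-0.123,,0.88,dec
RL,Root length,linear,-0.0696,1.078,,0.94,dec
RSA,Root surface area,linear,-0.0698,1.087,,0.93,dec
RV,Root volume,linear,-0.0699,1.096,,0.94,dec
RWD,Root dry weight,quadratic,0.0038,-0.122,1.1,0.95,dec
RT,Root tips,quadratic,0.0028,-0.093,1.128,0.86,dec
RC,Root crossings,quadratic,0.002,-0.107,1.059,0.98,dec
CHL,Chlorophyll,linear,0.98,0.0055,,0.75,dec
FL,Flavonoid index,linear,0.80,0.015,,0.41,inc
AN,Anthocyanin,linear,0.79,0.012,,0.57,inc
NBI,Nitrogen balance index,linear,0.98,0.020,,0.74,dec
P,Leaf photosynthesis,linear,1.2,-0.051,,0.59,dec
E,Transpiration,linear,1.4,-0.065,,0.58,dec
Ci/Ca,Ratio of intercellular and ambient CO2 concentrations,linear,1.1,-0.021,,0.51,dec
Gs,Stomatal conductance,linear,1.4,-0.069,,0.59,dec
ETR,Photosynthetic electron transport rate,linear,1.1,-0.028,,0.72,dec
phiPS2,PSII actual photochemical quantum yield,linear,1.2,-0.049,,0.71,dec
NPQ,Nonphotochemical chlorophyll fluorescence quenching,linear,0.051,0.052,,0.77,inc
Fv'/Fm',PSII effective chlorophyll fluorescence,linear,1.1,-0.013,,0.80,dec
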