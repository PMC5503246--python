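# Reconstructed Adriatic-Ionian case-study uncertainty matrix: sub-locations.
# Structure (5 locations / 17 sub-locations) rebuilt from the narrative account
# of the case study; a stand-in fixture, not a verbatim copy of the survey tables.
id,location,name
C1,context,Geographical domain of the planning macro-region
C2,context,Static temporal frame (single reference year; no seasonal dynamics)
M1,model,Pressure dispersion without oceanographic circulation modelling
M2,model,Representativeness of the spatial pressure models on components
M3,model,Baseline environmental conditions not considered
M4,model,Response of components to pressures assumed homogeneous
I1,inputs,Missing human-use datasets
I2,inputs,Limited component coverage in the Ionian basin
I3,inputs,Dataset proxies for mobile species
I4,inputs,Seabed-habitat dataset reliability
I5,inputs,Use-pressure-component sensitivity scores from expert survey
I6,inputs,Land-based pollution not represented
P1,parameters,Grid resolution versus dataset resolution
P2,parameters,Number of significant pressures per use-component pair
P3,parameters,Log-normalization of skewed intensity datasets
O1,outcome,Combination and dispersion of input statistical uncertainty
O2,outcome,Multi-stressor combination mechanisms and ecological significance
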