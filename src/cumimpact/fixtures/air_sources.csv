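# Reconstructed Adriatic-Ionian case-study uncertainty matrix: 31 sources.
# Level in {statistical, scenario, ignorance}; nature in {epistemic, variability};
# provenance M = modelers, SE = stakeholders and experts, L = literature.
sublocation_id,level,nature,provenance,description
C1,scenario,epistemic,M,Macro-region boundary chosen by policy rather than by ecosystem extent
C2,scenario,variability,SE,Seasonal dynamics of spawning areas and mobile species not represented
C2,scenario,epistemic,M,Single static reference year for all intensity layers
M1,scenario,epistemic,L,Surface circulation not represented in pressure spreading
M1,scenario,epistemic,L,Deep-basin exchange between sub-basins not represented
M1,ignorance,epistemic,L,Exchange with bordering marine areas unquantified
M2,scenario,epistemic,M,Gaussian spreading as a proxy for pressure-specific dispersion
M2,scenario,variability,SE,Pressure reach varies with local conditions not captured by one distance
M3,scenario,epistemic,M,Impacts assessed without baseline environmental state
M4,scenario,variability,SE,Component response varies in space but is modelled as homogeneous
M4,ignorance,variability,L,Resilience levels and regime shifts unresolved in the literature
M4,ignorance,epistemic,L,Functional form of the dose-response relationship unknown
I1,scenario,epistemic,M,Several human-use datasets unavailable for parts of the domain
I2,scenario,epistemic,M,Marine-mammal coverage missing in the Ionian basin
I2,scenario,epistemic,M,Giant-devil-ray coverage missing in the Ionian basin
I3,scenario,variability,SE,Proxy distributions for mobile species stand in for observations
I3,statistical,epistemic,L,Sampling error in the mobile-species proxy surfaces
I4,statistical,epistemic,L,Classification error in the broad-scale seabed-habitat map
I5,scenario,variability,SE,Expert sensitivity judgements differ among respondents
I5,ignorance,variability,SE,Sensitivities unknown for deep-sea and seabird relationships
I5,ignorance,epistemic,SE,Ecological meaning of the elicited sensitivity scale
I5,statistical,epistemic,SE,Survey sample size limits score precision
I6,scenario,epistemic,M,Land-based pollution sources absent from the use inventory
P1,statistical,epistemic,M,Grid cell size coarser than several source datasets
P2,scenario,epistemic,M,Choice of how many pressures per use-component pair are significant
P3,scenario,epistemic,M,Log-normalization choice for skewed intensity layers
O1,statistical,epistemic,M,Propagation of input statistical error into the index
O1,statistical,variability,M,Dispersion of combined spatial models across relationships
O2,ignorance,variability,L,Synergistic or mitigative multi-stressor mechanisms unresolved
O2,ignorance,epistemic,L,Ecological significance of low chronic index signals
O2,scenario,variability,SE,Population-level effects of widespread low impacts
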