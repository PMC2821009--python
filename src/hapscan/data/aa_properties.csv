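property,amino_acid,value
hydropathy,A,1.8
hydropathy,R,-4.5
hydropathy,N,-3.5
hydropathy,D,-3.5
hydropathy,C,2.5
hydropathy,Q,-3.5
hydropathy,E,-3.5
hydropathy,G,-0.4
hydropathy,H,-3.2
hydropathy,I,4.5
hydropathy,L,3.8
hydropathy,K,-3.9
hydropathy,M,1.9
hydropathy,F,2.8
hydropathy,P,-1.6
hydropathy,S,-0.8
hydropathy,T,-0.7
hydropathy,W,-0.9
hydropathy,Y,-1.3
hydropathy,V,4.2
isoelectric_point,A,6.00
isoelectric_point,R,10.76
isoelectric_point,N,5.41
isoelectric_point,D,2.77
isoelectric_point,C,5.07
isoelectric_point,Q,5.65
isoelectric_point,E,3.22
isoelectric_point,G,5.97
isoelectric_point,H,7.59
isoelectric_point,I,6.02
isoelectric_point,L,5.98
isoelectric_point,K,9.74
isoelectric_point,M,5.74
isoelectric_point,F,5.48
isoelectric_point,P,6.30
isoelectric_point,S,5.68
isoelectric_point,T,5.60
isoelectric_point,W,5.89
isoelectric_point,Y,5.66
isoelectric_point,V,5.96
molecular_weight,A,89.09
molecular_weight,R,174.20
molecular_weight,N,132.12
molecular_weight,D,133.10
molecular_weight,C,121.16
molecular_weight,Q,146.15
molecular_weight,E,147.13
molecular_weight,G,75.07
molecular_weight,H,155.16
molecular_weight,I,131.17
molecular_weight,L,131.17
molecular_weight,K,146.19
molecular_weight,M,149.21
molecular_weight,F,165.19
molecular_weight,P,115.13
molecular_weight,S,105.09
molecular_weight,T,119.12
molecular_weight,W,204.23
molecular_weight,Y,181.19
molecular_weight,V,117.15
molecular_volume,A,31.0
molecular_volume,R,124.0
molecular_volume,N,56.0
molecular_volume,D,54.0
molecular_volume,C,55.0
molecular_volume,Q,85.0
molecular_volume,E,83.0
molecular_volume,G,3.0
molecular_volume,H,96.0
molecular_volume,I,111.0
molecular_volume,L,111.0
molecular_volume,K,119.0
molecular_volume,M,105.0
molecular_volume,F,132.0
molecular_volume,P,32.5
molecular_volume,S,32.0
molecular_volume,T,61.0
molecular_volume,W,170.0
molecular_volume,Y,136.0
molecular_volume,V,84.0
polarity,A,8.1
polarity,R,10.5
polarity,N,11.6
polarity,D,13.0
polarity,C,5.5
polarity,Q,10.5
polarity,E,12.3
polarity,G,9.0
polarity,H,10.4
polarity,I,5.2
polarity,L,4.9
polarity,K,11.3
polarity,M,5.7
polarity,F,5.2
polarity,P,8.0
polarity,S,9.2
polarity,T,8.6
polarity,W,5.4
polarity,Y,6.2
polarity,V,5.9
polar_requirement,A,7.0
polar_requirement,R,9.1
polar_requirement,N,10.0
polar_requirement,D,13.0
polar_requirement,C,4.8
polar_requirement,Q,8.6
polar_requirement,E,12.5
polar_requirement,G,7.9
polar_requirement,H,8.4
polar_requirement,I,4.9
polar_requirement,L,4.9
polar_requirement,K,10.1
polar_requirement,M,5.3
polar_requirement,F,5.0
polar_requirement,P,6.6
polar_requirement,S,7.5
polar_requirement,T,6.6
polar_requirement,W,5.2
polar_requirement,Y,5.4
polar_requirement,V,5.6
bulkiness,A,11.50
bulkiness,R,14.28
bulkiness,N,12.82
bulkiness,D,11.68
bulkiness,C,13.46
bulkiness,Q,14.45
bulkiness,E,13.57
bulkiness,G,3.40
bulkiness,H,13.69
bulkiness,I,21.40
bulkiness,L,21.40
bulkiness,K,15.71
bulkiness,M,16.25
bulkiness,F,19.80
bulkiness,P,17.43
bulkiness,S,9.47
bulkiness,T,15.77
bulkiness,W,21.67
bulkiness,Y,18.03
bulkiness,V,21.57
helix_propensity,A,1.42
helix_propensity,R,0.98
helix_propensity,N,0.67
helix_propensity,D,1.01
helix_propensity,C,0.70
helix_propensity,Q,1.11
helix_propensity,E,1.51
helix_propensity,G,0.57
helix_propensity,H,1.00
helix_propensity,I,1.08
helix_propensity,L,1.21
helix_propensity,K,1.16
helix_propensity,M,1.45
helix_propensity,F,1.13
helix_propensity,P,0.57
helix_propensity,S,0.77
helix_propensity,T,0.83
helix_propensity,W,1.08
helix_propensity,Y,0.69
helix_propensity,V,1.06
sheet_propensity,A,0.83
sheet_propensity,R,0.93
sheet_propensity,N,0.89
sheet_propensity,D,0.54
sheet_propensity,C,1.19
sheet_propensity,Q,1.10
sheet_propensity,E,0.37
sheet_propensity,G,0.75
sheet_propensity,H,0.87
sheet_propensity,I,1.60
sheet_propensity,L,1.30
sheet_propensity,K,0.74
sheet_propensity,M,1.05
sheet_propensity,F,1.38
sheet_propensity,P,0.55
sheet_propensity,S,0.75
sheet_propensity,T,1.19
sheet_propensity,W,1.37
sheet_propensity,Y,1.47
sheet_propensity,V,1.70
turn_propensity,A,0.66
turn_propensity,R,0.95
turn_propensity,N,1.56
turn_propensity,D,1.46
turn_propensity,C,1.19
turn_propensity,Q,0.98
turn_propensity,E,0.74
turn_propensity,G,1.56
turn_propensity,H,0.95
turn_propensity,I,0.47
turn_propensity,L,0.59
turn_propensity,K,1.01
turn_propensity,M,0.60
turn_propensity,F,0.60
turn_propensity,P,1.52
turn_propensity,S,1.43
turn_propensity,T,0.96
turn_propensity,W,0.96
turn_propensity,Y,1.14
turn_propensity,V,0.50
hydrophilicity,A,-0.5
hydrophilicity,R,3.0
hydrophilicity,N,0.2
hydrophilicity,D,3.0
hydrophilicity,C,-1.0
hydrophilicity,Q,0.2
hydrophilicity,E,3.0
hydrophilicity,G,0.0
hydrophilicity,H,-0.5
hydrophilicity,I,-1.8
hydrophilicity,L,-1.8
hydrophilicity,K,3.0
hydrophilicity,M,-1.3
hydrophilicity,F,-2.5
hydrophilicity,P,0.0
hydrophilicity,S,0.3
hydrophilicity,T,-0.4
hydrophilicity,W,-3.4
hydrophilicity,Y,-2.3
hydrophilicity,V,-1.5
consensus_hydrophobicity,A,0.62
consensus_hydrophobicity,R,-2.53
consensus_hydrophobicity,N,-0.78
consensus_hydrophobicity,D,-0.90
consensus_hydrophobicity,C,0.29
consensus_hydrophobicity,Q,-0.85
consensus_hydrophobicity,E,-0.74
consensus_hydrophobicity,G,0.48
consensus_hydrophobicity,H,-0.40
consensus_hydrophobicity,I,1.38
consensus_hydrophobicity,L,1.06
consensus_hydrophobicity,K,-1.50
consensus_hydrophobicity,M,0.64
consensus_hydrophobicity,F,1.19
consensus_hydrophobicity,P,0.12
consensus_hydrophobicity,S,-0.18
consensus_hydrophobicity,T,-0.05
consensus_hydrophobicity,W,0.81
consensus_hydrophobicity,Y,0.26
consensus_hydrophobicity,V,1.08
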