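participant,group,day,max_hr,max_workload,vo2_peak,rer,at_workload
ME007,case,1,178,135,25.4,1.24,60
ME007,case,2,172,120,26.1,1.13,45
ME016,case,1,184,195,34.4,1.09,105
ME016,case,2,188,195,33.2,1.11,60
ME024,case,1,187,135,29.1,1.12,75
ME024,case,2,171,135,31.6,1.19,75
ME026,case,1,197,210,30.1,1.13,135
ME026,case,2,189,180,29.0,1.04,150
ME028,case,1,157,180,35.1,1.25,90
ME028,case,2,138,165,31.1,1.30,120
CO12,control,1,188,285,49.4,1.20,195
CO12,control,2,191,285,50.7,1.17,210
C036,control,1,183,165,21.8,1.04,75
C036,control,2,181,165,22.0,1.17,75
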