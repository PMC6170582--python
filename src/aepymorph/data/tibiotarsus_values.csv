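code,taxon,value_mm
Tt1,Mullerornis modestus,435.0
Tt1,Aepyornis hildebrandti,473.0
Tt1,Aepyornis maximus,614.0
Tt2,Mullerornis modestus,20.5
Tt2,Aepyornis hildebrandti,39.3
Tt2,Aepyornis maximus,60.5
Tt2,Vorombe titan,75.8
Tt3,Mullerornis modestus,85.0
Tt3,Aepyornis hildebrandti,110.0
Tt3,Aepyornis maximus,165.0
Tt3,Vorombe titan,206
Tt4,Mullerornis modestus,28.2
Tt4,Aepyornis hildebrandti,26.8
Tt4,Aepyornis maximus,39.8
Tt4,Vorombe titan,44.3
Tt5,Mullerornis modestus,61.0
Tt5,Aepyornis hildebrandti,90.1
Tt5,Aepyornis maximus,129.0
Tt5,Vorombe titan,162.0
Tt6,Mullerornis modestus,45.5
Tt6,Aepyornis hildebrandti,59.3
Tt6,Aepyornis maximus,84.6
Tt6,Vorombe titan,112.5
Tt7,Mullerornis modestus,51.0
Tt7,Aepyornis hildebrandti,72.7
Tt7,Aepyornis maximus,100.4
Tt7,Vorombe titan,134.5
Tt8,Mullerornis modestus,91.0
Tt8,Aepyornis hildebrandti,128.8
Tt8,Aepyornis maximus,184.0
Tt9,Mullerornis modestus,57.0
Tt9,Aepyornis hildebrandti,85.5
Tt9,Aepyornis maximus,96.5
Tt10,Mullerornis modestus,65.0
Tt10,Aepyornis hildebrandti,93.9
Tt10,Aepyornis maximus,196.0
Tt11,Mullerornis modestus,48.0
Tt11,Aepyornis hildebrandti,30.4
Tt11,Aepyornis maximus,55.6
Tt12,Mullerornis modestus,40.8
Tt12,Aepyornis hildebrandti,65.6
Tt12,Aepyornis maximus,111.9
Tt13,Mullerornis modestus,57.2
Tt13,Aepyornis hildebrandti,59.2
Tt13,Aepyornis maximus,90.2
Tt14,Mullerornis modestus,59.8
Tt14,Aepyornis hildebrandti,70.9
Tt14,Aepyornis maximus,105.4
Tt16,Mullerornis modestus,34.0
Tt16,Aepyornis hildebrandti,53.5
Tt16,Aepyornis maximus,78.9
Tt17,Mullerornis modestus,28.0
Tt17,Aepyornis hildebrandti,28.0
Tt17,Aepyornis maximus,45.2
Tt18,Mullerornis modestus,15.2
Tt18,Aepyornis hildebrandti,18.6
Tt18,Aepyornis maximus,30.9
Tt19,Mullerornis modestus,25.0
Tt19,Aepyornis hildebrandti,43.3
Tt19,Aepyornis maximus,49.7
Tt20,Mullerornis modestus,63.0
Tt20,Aepyornis hildebrandti,71.6
Tt20,Aepyornis maximus,105.0
Tt21,Mullerornis modestus,96.0
Tt21,Aepyornis hildebrandti,153.0
Tt21,Aepyornis maximus,225.0
Tt21,Vorombe titan,263.0
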