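code,taxon,min_mm,max_mm,n
Tmt1,Mullerornis modestus,271.0,324.0,11
Tmt1,Aepyornis hildebrandti,288,346,18
Tmt1,Aepyornis maximus,352,385,5
Tmt1,Vorombe titan,419.0,486.0,5
Tmt2,Mullerornis modestus,15.0,20.3,11
Tmt2,Aepyornis hildebrandti,23.1,29.42,18
Tmt2,Aepyornis maximus,27.0,34.7,5
Tmt2,Vorombe titan,32.0,39.0,5
Tmt3,Mullerornis modestus,27.0,32.3,11
Tmt3,Aepyornis hildebrandti,50.5,65.0,18
Tmt3,Aepyornis maximus,63.3,69.2,5
Tmt3,Vorombe titan,76.9,87.2,5
Tmt4,Mullerornis modestus,27.2,37.6,11
Tmt4,Aepyornis hildebrandti,39.2,50.9,17
Tmt4,Aepyornis maximus,48.3,54.5,5
Tmt4,Vorombe titan,59.8,62.7,5
Tmt5,Mullerornis modestus,65.0,79.3,11
Tmt5,Aepyornis hildebrandti,105.7,118.5,18
Tmt5,Aepyornis maximus,125.2,140.2,5
Tmt5,Vorombe titan,164.0,178.0,5
Tmt6,Mullerornis modestus,27.9,39.5,11
Tmt6,Aepyornis hildebrandti,34.1,59.9,16
Tmt6,Aepyornis maximus,46.44,58.6,5
Tmt6,Vorombe titan,61.6,67.8,5
Tmt7,Mullerornis modestus,24.0,30.4,11
Tmt7,Aepyornis hildebrandti,31.6,69.3,18
Tmt7,Aepyornis maximus,46.4,54.7,5
Tmt7,Vorombe titan,52.9,68.0,4
Tmt8,Mullerornis modestus,26.3,44.7,10
Tmt8,Aepyornis hildebrandti,24.5,69.7,18
Tmt8,Aepyornis maximus,71.8,87.8,5
Tmt8,Vorombe titan,74.7,95.3,4
Tmt9,Mullerornis modestus,65.8,81.5,11
Tmt9,Aepyornis hildebrandti,47.8,123.1,18
Tmt9,Aepyornis maximus,140.3,150.5,4
Tmt9,Vorombe titan,173.0,184.0,5
Tmt10,Mullerornis modestus,54.0,67.3,11
Tmt10,Aepyornis hildebrandti,78.1,110.6,18
Tmt10,Aepyornis maximus,108.3,118.7,4
Tmt10,Vorombe titan,131.1,153.0,5
Tmt11,Mullerornis modestus,64.0,75.3,11
Tmt11,Aepyornis hildebrandti,99.8,114.1,18
Tmt11,Aepyornis maximus,120.5,140.1,5
Tmt11,Vorombe titan,161.0,173.0,5
Tmt12,Mullerornis modestus,17.6,25.9,11
Tmt12,Aepyornis hildebrandti,21.9,31.1,17
Tmt12,Aepyornis maximus,32.5,36.8,5
Tmt12,Vorombe titan,33.9,48.9,5
Tmt13,Mullerornis modestus,26.4,34.2,11
Tmt13,Aepyornis hildebrandti,35.6,48.5,17
Tmt13,Aepyornis maximus,44.6,54.2,5
Tmt13,Vorombe titan,54.8,61.7,5
Tmt14,Mullerornis modestus,21.3,27.4,10
Tmt14,Aepyornis hildebrandti,38.4,45.8,18
Tmt14,Aepyornis maximus,44.8,55.5,5
Tmt14,Vorombe titan,59.1,81.6,4
Tmt15,Mullerornis modestus,19.7,27.6,11
Tmt15,Aepyornis hildebrandti,34.2,39.3,18
Tmt15,Aepyornis maximus,43.7,50.7,4
Tmt15,Vorombe titan,54.9,73.7,4
Tmt16,Mullerornis modestus,21.3,27.9,10
Tmt16,Aepyornis hildebrandti,38.7,47.3,18
Tmt16,Aepyornis maximus,49.8,53.9,4
Tmt16,Vorombe titan,57.3,66.7,4
Tmt17,Mullerornis modestus,30.0,37.2,11
Tmt17,Aepyornis hildebrandti,44.26,54.24,16
Tmt17,Aepyornis maximus,61,66.1,5
Tmt17,Vorombe titan,64.1,83.1,4
Tmt18,Mullerornis modestus,28.0,34.2,11
Tmt18,Aepyornis hildebrandti,38.2,47.1,16
Tmt18,Aepyornis maximus,50.7,62.1,5
Tmt18,Vorombe titan,68.8,76.8,4
Tmt19,Mullerornis modestus,26.2,38.2,11
Tmt19,Aepyornis hildebrandti,45.6,53.7,16
Tmt19,Aepyornis maximus,62.2,68.02,5
Tmt19,Vorombe titan,76.4,88.1,4
Tmt20,Mullerornis modestus,25.4,31.0,11
Tmt20,Aepyornis hildebrandti,38.9,52.6,18
Tmt20,Aepyornis maximus,50.3,56.2,5
Tmt20,Vorombe titan,63.7,80.4,4
Tmt21,Mullerornis modestus,22.0,25.8,10
Tmt21,Aepyornis hildebrandti,32.5,45.8,18
Tmt21,Aepyornis maximus,45.4,50.6,5
Tmt21,Vorombe titan,55.4,89.8,4
Tmt22,Mullerornis modestus,19.0,29.9,10
Tmt22,Aepyornis hildebrandti,35.7,42.7,18
Tmt22,Aepyornis maximus,48,53.5,5
Tmt22,Vorombe titan,55.2,70.0,4
Tmt23,Mullerornis modestus,20.0,34.6,9
Tmt23,Aepyornis hildebrandti,47.5,56.3,18
Tmt23,Aepyornis maximus,55.6,70.6,5
Tmt23,Vorombe titan,61.5,81.4,5
Tmt24,Mullerornis modestus,23.0,36.3,10
Tmt24,Aepyornis hildebrandti,43.9,53.6,18
Tmt24,Aepyornis maximus,52.9,61.7,5
Tmt24,Vorombe titan,65.2,73.5,5
Tmt25,Mullerornis modestus,24.6,33.4,11
Tmt25,Aepyornis hildebrandti,35.0,46.2,18
Tmt25,Aepyornis maximus,47.5,58.1,5
Tmt25,Vorombe titan,59.2,65.3,5
Tmt26,Mullerornis modestus,35.0,47.5,9
Tmt26,Aepyornis hildebrandti,42.3,61.5,18
Tmt26,Aepyornis maximus,55.8,65.1,5
Tmt26,Vorombe titan,68.6,85.5,5
Tmt27,Mullerornis modestus,34.0,68.8,11
Tmt27,Aepyornis hildebrandti,50.6,62.1,18
Tmt27,Aepyornis maximus,64.6,71.3,5
Tmt27,Vorombe titan,80.1,96.2,5
Tmt28,Mullerornis modestus,24.0,45.6,10
Tmt28,Aepyornis hildebrandti,49.5,64.3,17
Tmt28,Aepyornis maximus,53.6,73.4,5
Tmt28,Vorombe titan,77.2,100.1,5
Tmt29,Mullerornis modestus,20.5,30.3,10
Tmt29,Aepyornis hildebrandti,36.0,55.4,17
Tmt29,Aepyornis maximus,43.4,66.1,5
Tmt29,Vorombe titan,54.2,59.1,5
Tmt30,Mullerornis modestus,26.1,33.2,11
Tmt30,Aepyornis hildebrandti,40,51.8,18
Tmt30,Aepyornis maximus,51.1,56.4,5
Tmt30,Vorombe titan,53.6,70.6,5
Tmt31,Mullerornis modestus,26.8,35.3,11
Tmt31,Aepyornis hildebrandti,39.0,48.1,18
Tmt31,Aepyornis maximus,49.2,58.9,5
Tmt31,Vorombe titan,62.4,67.6,5
Tmt32,Mullerornis modestus,6.8,12.8,10
Tmt32,Aepyornis hildebrandti,8.8,17.2,17
Tmt32,Aepyornis maximus,14.5,20.2,5
Tmt32,Vorombe titan,14.1,24.6,5
Tmt33,Mullerornis modestus,56.0,67.4,10
Tmt33,Aepyornis hildebrandti,85.5,104.5,18
Tmt33,Aepyornis maximus,121.6,135.3,4
Tmt33,Vorombe titan,151.9,167.0,4
Tmt34,Mullerornis modestus,10.2,19.9,8
Tmt34,Aepyornis hildebrandti,14.8,25.2,16
Tmt34,Aepyornis maximus,21.1,33.4,5
Tmt34,Vorombe titan,26.1,36.4,3
Tmt35,Mullerornis modestus,32.6,45.6,11
Tmt35,Aepyornis hildebrandti,56.3,64.6,17
Tmt35,Aepyornis maximus,73.2,79.6,4
Tmt35,Vorombe titan,88.2,99.7,5
Tmt36,Mullerornis modestus,19.0,34.2,11
Tmt36,Aepyornis hildebrandti,38.5,50.5,17
Tmt36,Aepyornis maximus,45.1,53.1,5
Tmt36,Vorombe titan,50.8,69.8,5
Tmt37,Mullerornis modestus,18.2,33.6,8
Tmt37,Aepyornis hildebrandti,36.7,53.2,17
Tmt37,Aepyornis maximus,37.9,49,4
Tmt37,Vorombe titan,52.3,82.0,5
Tmt38,Mullerornis modestus,38.5,49.0,9
Tmt38,Aepyornis hildebrandti,55.7,71.4,17
Tmt38,Aepyornis maximus,72.5,76.9,5
Tmt38,Vorombe titan,73.4,93.0,3
Tmt39,Mullerornis modestus,44.0,53.8,9
Tmt39,Aepyornis hildebrandti,62.44,76.2,17
Tmt39,Aepyornis maximus,84.1,91.7,5
Tmt39,Vorombe titan,76.5,110.7,4
Tmt40,Mullerornis modestus,53.8,65.2,9
Tmt40,Aepyornis hildebrandti,82.8,101.1,17
Tmt40,Aepyornis maximus,112,120.2,4
Tmt40,Vorombe titan,127.0,137.0,4
Tmt41,Mullerornis modestus,271.0,300.0,11
Tmt41,Aepyornis hildebrandti,259,310,17
Tmt41,Aepyornis maximus,326,357,5
Tmt41,Vorombe titan,391.0,440.0,4
Tmt42,Mullerornis modestus,261.0,313.0,10
Tmt42,Aepyornis hildebrandti,258,333,17
Tmt42,Aepyornis maximus,356,372,4
Tmt42,Vorombe titan,380.0,447.0,5
Tmt43,Mullerornis modestus,263.0,317.0,10
Tmt43,Aepyornis hildebrandti,274,328,17
Tmt43,Aepyornis maximus,363,372,4
Tmt43,Vorombe titan,415.0,457.0,5
Tmt44,Mullerornis modestus,265.0,312.0,10
Tmt44,Aepyornis hildebrandti,284,334,17
Tmt44,Aepyornis maximus,312,381,5
Tmt44,Vorombe titan,414.0,459.0,4
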