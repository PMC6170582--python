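code,taxon,min_mm,max_mm,n
F1,Mullerornis modestus,245,268,5
F1,Aepyornis hildebrandti,307.0,347.0,18
F1,Aepyornis maximus,354.0,383.0,4
F1,Vorombe titan,437.0,490.0,8
F2,Mullerornis modestus,28.4,43.2,10
F2,Aepyornis hildebrandti,45.9,57.7,29
F2,Aepyornis maximus,51.3,69.5,8
F2,Vorombe titan,64.4,94.1,12
F3,Mullerornis modestus,114,158,10
F3,Aepyornis hildebrandti,172.0,210.0,29
F3,Aepyornis maximus,208.0,254.0,8
F3,Vorombe titan,253.0,288.0,10
F4,Mullerornis modestus,36.8,52.7,10
F4,Aepyornis hildebrandti,56.0,68.5,29
F4,Aepyornis maximus,68.7,89.6,8
F4,Vorombe titan,66.8,99.5,12
F5,Mullerornis modestus,107,122,9
F5,Aepyornis hildebrandti,147.0,180.0,28
F5,Aepyornis maximus,181.0,220.0,7
F5,Vorombe titan,212.0,276.0,8
F6,Mullerornis modestus,31.3,42.8,9
F6,Aepyornis hildebrandti,45.9,57.3,29
F6,Aepyornis maximus,51.4,67.6,6
F6,Vorombe titan,66.3,79.2,8
F7,Mullerornis modestus,32.5,44.3,9
F7,Aepyornis hildebrandti,46.6,56.5,29
F7,Aepyornis maximus,56.8,69.9,6
F7,Vorombe titan,67.1,79.9,9
F8,Mullerornis modestus,63.8,89.4,8
F8,Aepyornis hildebrandti,90.6,140.8,20
F8,Aepyornis maximus,122.7,135.5,2
F8,Vorombe titan,139.2,181.0,6
F9,Mullerornis modestus,90.7,100.0,8
F9,Aepyornis hildebrandti,87.3,142.2,26
F9,Aepyornis maximus,150,167,4
F9,Vorombe titan,182.0,207.0,8
F10,Mullerornis modestus,50.9,57.6,5
F10,Aepyornis hildebrandti,79.4,98.3,18
F10,Aepyornis maximus,96.86,97.4,2
F10,Vorombe titan,79.9,126.0,5
F11,Mullerornis modestus,56.6,70.6,8
F11,Aepyornis hildebrandti,82.7,105.3,23
F11,Aepyornis maximus,107.9,118.0,5
F11,Vorombe titan,118.9,149.0,9
F12,Mullerornis modestus,221,233,5
F12,Aepyornis hildebrandti,233.0,309.0,17
F12,Aepyornis maximus,312.0,329.0,3
F12,Vorombe titan,374.0,426.0,8
F13,Mullerornis modestus,228,265,4
F13,Aepyornis hildebrandti,250.0,327.0,16
F13,Aepyornis maximus,328.0,358.0,3
F13,Vorombe titan,392.0,445.0,8
F14,Mullerornis modestus,231,253,7
F14,Aepyornis hildebrandti,232.0,326.0,25
F14,Aepyornis maximus,332.0,364.0,3
F14,Vorombe titan,399.0,453.0,8
F15,Mullerornis modestus,196,208,7
F15,Aepyornis hildebrandti,244.0,282.0,23
F15,Aepyornis maximus,290,350,4
F15,Vorombe titan,325.0,375.0,9
F16,Mullerornis modestus,87.2,109.2,10
F16,Aepyornis hildebrandti,121.4,151.6,24
F16,Aepyornis maximus,114.0,151.0,3
F16,Vorombe titan,177.0,202.0,8
F17,Mullerornis modestus,74.1,103.9,8
F17,Aepyornis hildebrandti,89.7,147.6,24
F17,Aepyornis maximus,130.4,132.6,2
F17,Vorombe titan,156.0,171.0,6
F18,Mullerornis modestus,86.5,110.7,8
F18,Aepyornis hildebrandti,102.8,148.6,26
F18,Aepyornis maximus,143.6,166.0,3
F18,Vorombe titan,143.0,210.0,7
F19,Mullerornis modestus,18.9,27.8,6
F19,Aepyornis hildebrandti,20.5,34.8,26
F19,Aepyornis maximus,26.3,35.9,6
F19,Vorombe titan,32.0,44.0,9
F20,Mullerornis modestus,8.4,11.7,9
F20,Aepyornis hildebrandti,12.7,29.2,26
F20,Aepyornis maximus,13.7,23.5,9
F20,Vorombe titan,18.5,29.6,11
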