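wavelength_nm,S0,S1,S2
380,63.4,38.5,3.0
390,65.8,35.0,1.2
400,94.8,43.4,-1.1
410,104.8,46.3,-0.5
420,105.9,43.9,-0.7
430,96.8,37.1,-1.2
440,113.9,36.7,-2.6
450,125.6,35.9,-2.9
460,125.5,32.6,-2.8
470,121.3,27.9,-2.6
480,121.3,24.3,-2.6
490,113.5,20.1,-1.8
500,113.1,16.2,-1.5
510,110.8,13.2,-1.3
520,106.5,8.6,-1.2
530,108.8,6.1,-1.0
540,105.3,4.2,-0.5
550,104.4,1.9,-0.3
560,100.0,0.0,0.0
570,96.0,-1.6,0.2
580,95.1,-3.5,0.5
590,89.1,-3.5,2.1
600,90.5,-5.8,3.2
610,90.3,-7.2,4.1
620,88.4,-8.6,4.7
630,84.0,-9.5,5.1
640,85.1,-10.9,6.7
650,81.9,-10.7,7.3
660,82.6,-12.0,8.6
670,84.9,-14.0,9.8
680,81.3,-13.6,10.2
690,71.9,-12.0,8.3
700,74.3,-13.3,9.6
710,76.4,-12.9,8.5
720,63.3,-10.6,7.0
730,71.7,-11.6,7.6
740,77.0,-12.2,8.0
750,65.2,-10.2,6.7
760,47.7,-7.8,5.2
770,68.6,-11.2,7.4
780,65.0,-10.4,6.8
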