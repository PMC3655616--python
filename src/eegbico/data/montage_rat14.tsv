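# Rat epidural 14-screw montage, planar coordinates in mm relative to bregma
# (anterior positive, lateral right positive). Scalp electrodes follow the
# published coordinate list for this montage; the "A +/-1.5" notation for the
# centrofrontal group is resolved as FL2/FR2 anterior (+1.5) and PL1/PR1
# posterior (-1.5). REF/GND sit 2 and 4 mm caudal to lambda; lambda is not
# given in the same coordinate frame, so a 9 mm bregma-lambda distance is
# assumed for their rows. REF/GND are excluded from topographic maps.
label	anterior_mm	lateral_mm
FL1	4.5	-1.5
FR1	4.5	1.5
FL2	1.5	-4.5
FR2	1.5	4.5
PL1	-1.5	-4.5
PR1	-1.5	4.5
PL2	0.0	-4.5
PR2	0.0	4.5
LFL	-4.5	-1.5
RFR	-4.5	1.5
LPL	-3.0	-4.5
RPR	-3.0	4.5
REF	-11.0	0.0
GND	-13.0	0.0
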