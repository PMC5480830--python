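microRNA	variant	position	species
miR-26b-5p	T > C	11	galago
miR-501-3p	C > T	9	mouse lemur, galago
miR-28-5p	G > A	12	squirrel monkey
miR-28-5p	G > A	10	galago
miR-34b-5p	C > A	10	mouse lemur, galago
miR-193b-5p	T > A	10	mouse lemur, aye-aye, galago
miR-532-5p	C > T	20	galago
miR-151b-3p	A > G	10	mouse lemur
miR-151b-3p	G > A	11	squirrel monkey
miR-328	T > C	22	mouse lemur
miR-299-3p	C > T	10	human
miR-224-5p	G > A	19	squirrel monkey
miR-195-5p	A > T	10	galago
miR-450b-5p	A > T	10	squirrel monkey
miR-2355-5p	C > T	15	orangutan
miR-374a-5p	T > C	21	galago
miR-539-5p	T > C	21	squirrel monkey
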