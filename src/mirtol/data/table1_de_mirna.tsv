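feature_id	log2fc	direction
mghv miR-M1-9	4.38	up
miR-202-5p	4.07	up
miR-194	3.46	up
miR-29b*	2.44	up
miR-672	2.21	up
miR-197	2.13	up
miR-467a-1*	1.94	up
miR-30b*	1.83	up
miR-126-5p	1.76	up
miR-152	1.62	up
miR-469	1.55	up
miR-184	1.46	up
miR-378*	1.37	up
miR-669a	1.30	up
miR-92b	1.26	up
let-7d*	1.26	up
miR-505	1.12	up
miR-101b	1.05	up
miR-429	0.95	up
miR-490	0.74	up
miR-320	0.73	up
miR-22*	0.72	up
miR-574-3p	0.68	up
miR-342-5p	0.67	up
miR-376a	0.60	up
miR-483*	0.58	up
miR-700	0.55	up
miR-298	0.54	up
miR-690	0.53	up
miR-380-3p	0.46	up
miR-376b	0.43	up
miR-423-5p	0.41	up
miR-335-3p	0.38	up
miR-382*	-1.81	down
miR-154*	-1.49	down
miR-29b	-0.69	down
miR-19b	-0.68	down
miR-338-3p	-0.59	down
miR-199b	-0.57	down
miR-1	-0.52	down
miR-34c	-0.48	down
miR-146a	-0.47	down
miR-218	-0.40	down
miR-27a	-0.37	down
miR-9	-0.37	down
miR-872	-0.35	down
miR-146b	-0.34	down
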