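mirna_id	mirna_direction	mirna_log2	mrna_id	mirsvr	mrna_direction	missing
mmu-miR-146b	down	-0.3362	Gripap1	-0.6473	down	False
mmu-miR-146b	down	-0.3362	Fstl1	-0.4896	down	False
mmu-miR-146b	down	-0.3362	Dlgap1	-0.4727	down	False
mmu-miR-146b	down	-0.3362	Vps26a	-0.2555	down	False
mmu-miR-146b	down	-0.3362	Gosr2	-0.1763	down	False
mmu-miR-146b	down	-0.3362	Gprasp1	-0.1232	down	False
mmu-miR-146b	down	-0.3362	Zfand6	-0.1105	down	False
mmu-miR-146b	down	-0.3362	Serpini1	-0.1097	down	False
mmu-miR-27a	down	-0.3670			down	True
mmu-miR-27a	down	-0.3670	Ppp1r9a	-0.8020	down	False
mmu-miR-27a	down	-0.3670	Ubqln1	-0.7975	down	False
mmu-miR-27a	down	-0.3670	Rps6ka5	-0.7940	down	False
mmu-miR-27a	down	-0.3670	Gosr2	-0.7700	down	False
mmu-miR-27a	down	-0.3670	Canx	-0.7310	down	False
mmu-miR-27a	down	-0.3670	AI593442	-0.5274	down	False
mmu-miR-27a	down	-0.3670	Nsf	-0.4902	down	False
mmu-miR-27a	down	-0.3670	Dgkb	-0.4384	down	False
mmu-miR-27a	down	-0.3670	Dlgap1	-0.3411	down	False
mmu-miR-27a	down	-0.3670	Atp2b2	-0.2743	down	False
mmu-miR-27a	down	-0.3670	Zfand6	-0.1456	down	False
mmu-miR-27a	down	-0.3670	Nufip1	-0.1278	down	False
mmu-miR-505	up	1.1166	Sap25	-1.2974	up	False
mmu-miR-505	up	1.1166	Parp11	-1.0018	up	False
mmu-miR-505	up	1.1166	Srbd1	-0.6136	up	False
mmu-miR-505	up	1.1166	Dicer1	-0.3529	up	False
mmu-miR-505	up	1.1166	Txnip	-0.2797	up	False
mmu-miR-505	up	1.1166	Phf17	-0.1855	up	False
mmu-miR-505	up	1.1166	Ccnf	-0.1480	up	False
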