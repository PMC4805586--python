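mirna_id	mirna_direction	mirna_log2	mrna_id	mirsvr	mrna_direction	missing
mmu-miR-146b	down	-0.3362	Enpp5	-1.0510	up	False
mmu-miR-146b	down	-0.3362	Pet112l	-1.0474	up	False
mmu-miR-146b	down	-0.3362	Afmid	-1.0327	up	False
mmu-miR-146b	down	-0.3362	Ccna2	-0.6094	up	False
mmu-miR-146b	down	-0.3362	Baiap2l1	-0.3049	up	False
mmu-miR-146b	down	-0.3362	Phf17	-0.2832	up	False
mmu-miR-146b	down	-0.3362	Pcbp2	-0.1396	up	False
mmu-miR-146b	down	-0.3362	Dicer1	-0.1357	up	False
mmu-miR-146b	down	-0.3362	C86695	-0.1061	up	False
mmu-miR-202-5p	up	4.0723	Dlgap1	-1.2131	down	False
mmu-miR-202-5p	up	4.0723	AI593442	-1.0566	down	False
mmu-miR-202-5p	up	4.0723	Rps6ka5	-0.9715	down	False
mmu-miR-202-5p	up	4.0723	Meis1	-0.7075	down	False
mmu-miR-202-5p	up	4.0723	Fstl1	-0.6275	down	False
mmu-miR-202-5p	up	4.0723	Atp2b2	-0.4273	down	False
mmu-miR-202-5p	up	4.0723	Rab6b	-0.2834	down	False
mmu-miR-202-5p	up	4.0723	Ubqln1	-0.1476	down	False
mmu-miR-202-5p	up	4.0723	Ppp1r9a	-0.1379	down	False
mmu-miR-202-5p	up	4.0723	Ralgps1	-0.1185	down	False
mmu-miR-27a	down	-0.3690	Fmn2	-0.7565	up	False
mmu-miR-27a	down	-0.3690	Dicer1	-0.7044	up	False
mmu-miR-27a	down	-0.3690	Rufy3	-0.6805	up	False
mmu-miR-27a	down	-0.3690	Dusp9	-0.3455	up	False
mmu-miR-27a	down	-0.3690	Baiap2l1	-0.2262	up	False
mmu-miR-505	up	1.1166	Meis1	-1.2283	down	False
mmu-miR-505	up	1.1166	Serpini1	-0.8085	down	False
mmu-miR-505	up	1.1166	Ralgps1	-0.4115	down	False
mmu-miR-505	up	1.1166	Canx	-0.3364	down	False
mmu-miR-505	up	1.1166	Hic2	-0.2643	down	False
mmu-miR-505	up	1.1166	Kcnj4	-0.1538	down	False
mmu-miR-505	up	1.1166	Vps26a	-0.1231	down	False
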