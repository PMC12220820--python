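gene	types	provenance
Acsl4	ferroptosis	synthetic stand-in panel
Aim2	pyroptosis	synthetic stand-in panel
Alox15	ferroptosis	synthetic stand-in panel
Alox5	ferroptosis	synthetic stand-in panel
Ambra1	autophagy	synthetic stand-in panel
Apaf1	apoptosis	synthetic stand-in panel
Atf3	apoptosis	synthetic stand-in panel
Atg12	autophagy	synthetic stand-in panel
Atg16l1	autophagy	synthetic stand-in panel
Atg5	autophagy	synthetic stand-in panel
Atg7	autophagy	synthetic stand-in panel
Bad	apoptosis	synthetic stand-in panel
Bak1	apoptosis	synthetic stand-in panel
Bax	apoptosis	synthetic stand-in panel
Bcl2	apoptosis	synthetic stand-in panel
Bcl2l1	apoptosis	synthetic stand-in panel
Becn1	autophagy	synthetic stand-in panel
Bid	apoptosis	synthetic stand-in panel
Casp1	pyroptosis	synthetic stand-in panel
Casp3	apoptosis	synthetic stand-in panel
Casp4	pyroptosis	synthetic stand-in panel
Casp7	apoptosis	synthetic stand-in panel
Casp8	apoptosis;necroptosis;pyroptosis	synthetic stand-in panel
Casp9	apoptosis	synthetic stand-in panel
Cd68	lysosome_dependent_cell_death	synthetic stand-in panel
Cd84	pyroptosis	synthetic stand-in panel
Cdc42	entotic_cell_death	synthetic stand-in panel
Cdh1	entotic_cell_death	synthetic stand-in panel
Ctnnb1	entotic_cell_death	synthetic stand-in panel
Ctsb	lysosome_dependent_cell_death	synthetic stand-in panel
Ctsd	lysosome_dependent_cell_death	synthetic stand-in panel
Ctsl	lysosome_dependent_cell_death	synthetic stand-in panel
Cycs	apoptosis	synthetic stand-in panel
Diablo	apoptosis	synthetic stand-in panel
Fadd	necroptosis	synthetic stand-in panel
Fas	apoptosis	synthetic stand-in panel
Faslg	apoptosis	synthetic stand-in panel
Fth1	ferroptosis	synthetic stand-in panel
Ftl1	ferroptosis	synthetic stand-in panel
Gabarapl1	autophagy	synthetic stand-in panel
Gsdmd	pyroptosis	synthetic stand-in panel
Il1b	pyroptosis	synthetic stand-in panel
Myc	apoptosis	synthetic stand-in panel
Pcds0001	apoptosis;ferroptosis	synthetic stand-in panel
Pcds0002	apoptosis	synthetic stand-in panel
Pcds0003	apoptosis	synthetic stand-in panel
Pcds0004	apoptosis	synthetic stand-in panel
Pcds0005	apoptosis	synthetic stand-in panel
Pcds0006	apoptosis	synthetic stand-in panel
Pcds0007	apoptosis;ferroptosis	synthetic stand-in panel
Pcds0008	apoptosis	synthetic stand-in panel
Pcds0009	apoptosis	synthetic stand-in panel
Pcds0010	apoptosis	synthetic stand-in panel
Pcds0011	apoptosis	synthetic stand-in panel
Pcds0012	apoptosis	synthetic stand-in panel
Pcds0013	apoptosis;ferroptosis	synthetic stand-in panel
Pcds0014	apoptosis	synthetic stand-in panel
Pcds0015	apoptosis	synthetic stand-in panel
Pcds0016	apoptosis	synthetic stand-in panel
Pcds0017	apoptosis	synthetic stand-in panel
Pcds0018	apoptosis	synthetic stand-in panel
Pcds0019	apoptosis;ferroptosis	synthetic stand-in panel
Pcds0020	apoptosis	synthetic stand-in panel
Ripk1	necroptosis	synthetic stand-in panel
Ripk3	necroptosis	synthetic stand-in panel
Stat6	apoptosis	synthetic stand-in panel
Tnf	apoptosis;necroptosis	synthetic stand-in panel
Zbp1	necroptosis	synthetic stand-in panel
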