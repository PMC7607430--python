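enzyme	substrate	product	constraint	constraint_licorrice
ManI	(Ma2Ma	(Ma	!@2Ma3(...Ma6)Ma6 & !Ga3	nMan(a1-?)>4 & nMan(a1-?)<8 & !Man(a1-2)Man(a1-3)...Man(a1-6) & !Glc(a1-3)
ManI	(Ma3(Ma2Ma3(Ma6)Ma6)	(Ma3(Ma3(Ma6)Ma6)	!Ga3	!Glc(a1-3)
ManII	(Ma3(Ma6)Ma6	(Ma6Ma6	(GNb2+Ma3 & !Gnbis	!Gal(b1-?) & !GlcNAc(b1-4)...Man(b1-4) & GlcNAc(b1-2)Man(a1-3)
ManII	(Ma6Ma6	(Ma6	(GNb2+Ma3 & !Gnbis
a6FucT	GNb4GN	GNb4(Fa6)GN	GNb2+Ma3 & #A=0 & !Gnbis	GlcNAc(b1-2)Man(a1-3)...Man(b1-4) & !GlcNAc(b1-4)...Man(b1-4) & !Fuc(a1-3)
GnTI	(Ma3(Ma3(Ma6)Ma6)Mb4	(GNb2Ma3(Ma3(Ma6)Ma6)Mb4		nMan(a1-?)=4
GnTII	(GNb2+Ma3(Ma6)Mb4	(GNb2+Ma3(GNb2Ma6)Mb4		nMan(a1-?)=2 & !GlcNAc(b1-4)...Man(b1-4) & !Fuc(a1-3) & !Gal(b1-?)
GnTIII	GNb2+Ma3	GNb2+Ma3(GNb4)	!Ab & !Gnbis	GlcNAc(b1-2)Man(a1-3)...Man(b1-4) & !Gal(b1-?)
GnTIV	(GNb2Ma3	(GNb2(GNb4)Ma3	!Gnbis	!Gal(b1-?) & !GlcNAc(b1-4)...Man(b1-4)
GnTV	(GNb2Ma6	(GNb2(GNb6)Ma6	!Gnbis	!Gal(b1-?) & !GlcNAc(b1-4)...Man(b1-4)
iGnT	(Ab4GN	(GNb3Ab4GN	!@_Ma3+Mb4
b4GalT	(GN	(Ab4GN	!@GNb4)(...Ma6)Mb4	!Gal(b1-3)GlcNAc(b1-?) & !@GlcNAc(b1-4)...Man(b1-4)
b3GalT	(GN	(Ab3GN	!@GNb4)(...Ma6)Mb4	!Gal(b1-4)GlcNAc(b1-?) & !@GlcNAc(b1-4)...Man(b1-4)
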