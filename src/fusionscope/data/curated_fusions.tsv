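# Curated fusions selected for in vivo functional testing, transcribed from
# the published summary table. Breakpoints were refined to base-pair
# resolution by Sanger sequencing and are stored verbatim.
# involvement grammar: "<Gene1|Gene2|Both> <CHOP|CCG>[ and <CHOP|CCG>]",
# naming which partner(s) sit on the clinical fusion panel (CHOP) and/or in
# the Cancer Gene Census (CCG).
# phenotype: "-" (none) or an "&"-joined subset of {VNC Area, VNC Length}.
fusion	breakpoint1	breakpoint2	grade	clinical_indication	involvement	phenotype
ABL1::WDR83OS	chr9:130874998	chr19:12668387	HGG	Recurrent IDH-mutant astrocytoma with primitive features, CNS WHO grade 4, >50% tumor	Gene1 CHOP and CCG	-
ACVR1B::CCDC60	chr12:51951833	chr12:119540614	LGG	IDH-mutant glioma (immunohistochemistry); 30-50% tumor	Gene1 CCG	-
ATG4B::CNTRL	chr2:241651335	chr9:121175018	HGG	Residual astrocytoma, IDH-mutant (immunohistochemistry), CNS WHO Grade 4. 30%-50% tumor	Gene2 CCG	-
BAZ1A::PI3	chr14:34874492	chr20:45175861	HGG	Diffuse midline glioma	Gene1 CCG	VNC Length
BSG::GNAS	chr19:572701	chr20:58895612	LGG	Desmoplastic infantile ganglioglioma (DIG), WHO Grade 1, >50% tumor	Gene2 CCG	VNC Area
CDKN2A::PTPRD	chr9:21994139	chr9:8528779	HGG	High-grade astrocytoma, pending final integrated diagnosis. >50% tumor. Resulted as: diffuse midline glioma	Both CCG	-
CLDND1::WRN	chr3:98521133	chr8:31080867	HGG	Diffuse midline glioma H3 K27M-altered, corresponds to Grade 4 (by IHC); 30%-50% tumor	Gene2 CCG	VNC Area & VNC Length
DUSP22::APOE	chr6:348153	chr19:44909242	HGG	Recurrent/residual IDH-mutant astrocytoma. >50% tumor	Gene1 CHOP	VNC Area & VNC Length
MDM2::NUP107	chr12:68820374	chr12:68709238	HGG	High-grade glioma; >50% tumor	Gene1 CCG	VNC Area
OLIG2::CHTOP	chr21:33027161	chr1:153642324	LGG	Low-grade glioma, >50% tumor	Gene1 CCG	VNC Length
PRNP::CD74	chr20:4699367	chr5:150407253	LGG	Ganglioglioma, CNS WHO Grade 1; >50% tumor	Gene2 CCG	-
PTPRK::NOX3	chr6:128520259	chr6:155411359	LGG	Glial/glioneuronal neoplasm. >50% tumor. Resulted as: low-grade glial / glioneuronal neoplasm	Gene1 CCG	-
TCF12::CALM2	chr15:56921098	chr2:47170764	HGG	Recurrent/residual IDH-mutant astrocytoma. >50% tumor	Gene1 CHOP and CCG	VNC Length
THRAP3::UROD	chr1:36289258	chr1:45013639	LGG	Ganglioglioma, CNS WHO Grade 1; >50% tumor	Gene1 CCG	-
ZNF254::GNAS	chr19:24106643	chr20:58895612	HGG	Recurrent IDH-mutant astrocytoma with primitive features, CNS WHO grade 4, >50% tumor	Gene2 CCG	VNC Area
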