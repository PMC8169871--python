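gene	category
ACAT1	biosynthesis-pre-squalene
ACAT2	biosynthesis-pre-squalene
HMGCS1	biosynthesis-pre-squalene
HMGCR	biosynthesis-pre-squalene
MVK	biosynthesis-pre-squalene
PMVK	biosynthesis-pre-squalene
IDI1	biosynthesis-pre-squalene
IDI2	biosynthesis-pre-squalene
GGPPS1	biosynthesis-pre-squalene
FDPS	biosynthesis-pre-squalene
FDFT1	biosynthesis-pre-squalene
SQLE	biosynthesis-pre-squalene
LSS	biosynthesis-pre-squalene
CYP51A1	biosynthesis-post-squalene
TM7SF2	biosynthesis-post-squalene
SC4MOL	biosynthesis-post-squalene
SC5D	biosynthesis-post-squalene
DHCR24	biosynthesis-post-squalene
DHCR7	biosynthesis-post-squalene
CYP46A1	catabolism-enzymatic
CYP27A1	catabolism-enzymatic
CYP7A1	catabolism-enzymatic
CYP7B1	catabolism-enzymatic
CYP39A1	catabolism-enzymatic
CYP8B1	catabolism-enzymatic
CYP11A1	catabolism-enzymatic
CYP3A4	catabolism-enzymatic
CH25H	catabolism-enzymatic
HSD3B7	catabolism-enzymatic
SOAT1	esterification
LCAT	esterification
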