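# alias	canonical
# NADH dehydrogenase subunits
ND1	NAD1
ND2	NAD2
ND3	NAD3
ND4	NAD4
ND4L	NAD4L
ND5	NAD5
ND6	NAD6
NADH1	NAD1
NADH2	NAD2
NADH3	NAD3
NADH4	NAD4
NADH4L	NAD4L
NADH5	NAD5
NADH6	NAD6
NADHDEHYDROGENASESUBUNIT1	NAD1
NADHDEHYDROGENASESUBUNIT2	NAD2
NADHDEHYDROGENASESUBUNIT3	NAD3
NADHDEHYDROGENASESUBUNIT4	NAD4
NADHDEHYDROGENASESUBUNIT4L	NAD4L
NADHDEHYDROGENASESUBUNIT5	NAD5
NADHDEHYDROGENASESUBUNIT6	NAD6
# cytochrome c oxidase subunits
COI	COX1
COII	COX2
COIII	COX3
CO1	COX1
CO2	COX2
CO3	COX3
COXI	COX1
COXII	COX2
COXIII	COX3
CYTOCHROMECOXIDASESUBUNITI	COX1
CYTOCHROMECOXIDASESUBUNITII	COX2
CYTOCHROMECOXIDASESUBUNITIII	COX3
CYTOCHROMECOXIDASESUBUNIT1	COX1
CYTOCHROMECOXIDASESUBUNIT2	COX2
CYTOCHROMECOXIDASESUBUNIT3	COX3
# cytochrome b
COB	CYTB
CYB	CYTB
CYTOCHROMEB	CYTB
# ATP synthase subunits
ATPASE6	ATP6
ATPASE8	ATP8
ATPSYNTHASEF0SUBUNIT6	ATP6
ATPSYNTHASEF0SUBUNIT8	ATP8
ATPSYNTHASESUBUNIT6	ATP6
ATPSYNTHASESUBUNIT8	ATP8
# ribosomal RNAs
RRNS	12S
RRNL	16S
SRRNA	12S
LRRNA	16S
12SRRNA	12S
16SRRNA	16S
12SRIBOSOMALRNA	12S
16SRIBOSOMALRNA	16S
SMALLSUBUNITRIBOSOMALRNA	12S
LARGESUBUNITRIBOSOMALRNA	16S
# transfer RNAs (trnX one-letter forms)
TRNA	tRNA-Ala
TRNR	tRNA-Arg
TRNN	tRNA-Asn
TRND	tRNA-Asp
TRNC	tRNA-Cys
TRNQ	tRNA-Gln
TRNE	tRNA-Glu
TRNG	tRNA-Gly
TRNH	tRNA-His
TRNI	tRNA-Ile
TRNK	tRNA-Lys
TRNM	tRNA-Met
TRNF	tRNA-Phe
TRNP	tRNA-Pro
TRNT	tRNA-Thr
TRNW	tRNA-Trp
TRNY	tRNA-Tyr
TRNV	tRNA-Val
TRNLTAG	tRNA-Leu(TAG)
TRNLTAA	tRNA-Leu(TAA)
TRNSGCT	tRNA-Ser(GCT)
TRNSTGA	tRNA-Ser(TGA)
# three-letter tRNA forms (normalization strips dashes/parentheses)
TRNAALA	tRNA-Ala
TRNAARG	tRNA-Arg
TRNAASN	tRNA-Asn
TRNAASP	tRNA-Asp
TRNACYS	tRNA-Cys
TRNAGLN	tRNA-Gln
TRNAGLU	tRNA-Glu
TRNAGLY	tRNA-Gly
TRNAHIS	tRNA-His
TRNAILE	tRNA-Ile
TRNALYS	tRNA-Lys
TRNAMET	tRNA-Met
TRNAPHE	tRNA-Phe
TRNAPRO	tRNA-Pro
TRNATHR	tRNA-Thr
TRNATRP	tRNA-Trp
TRNATYR	tRNA-Tyr
TRNAVAL	tRNA-Val
TRNALEUTAG	tRNA-Leu(TAG)
TRNALEUTAA	tRNA-Leu(TAA)
TRNALEU1	tRNA-Leu(TAG)
TRNALEU2	tRNA-Leu(TAA)
TRNASERGCT	tRNA-Ser(GCT)
TRNASERTGA	tRNA-Ser(TGA)
TRNASER1	tRNA-Ser(GCT)
TRNASER2	tRNA-Ser(TGA)
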