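# Default gene-order template for the mitogenome simulator.
# One row per gene in genome order on the circle. `spacer_after` is the
# number of non-coding nucleotides between this gene and the next one
# (negative = the next gene overlaps this one's tail). `start_codon` and
# `stop_codon` apply to PCGs only. Gene lengths include the stop codon.
# The architecture emulates a typical caenogastropod mitogenome: 13 PCGs,
# 22 tRNAs, 2 rRNAs; a minority light-strand tRNA block (MYCWQGE + Thr);
# two larger spacers flanking COX3; three small overlaps whose upstream
# partner is always a tRNA.
name	class	strand	length	spacer_after	start_codon	stop_codon
COX1	PCG	+	1536	2	ATG	TAA
COX2	PCG	+	690	5	ATG	TAA
tRNA-Asp	TRNA	+	68	-3
ATP8	PCG	+	159	10	ATG	TAA
ATP6	PCG	+	699	8	ATG	TAA
tRNA-Met	TRNA	-	68	6
tRNA-Tyr	TRNA	-	68	9
tRNA-Cys	TRNA	-	68	4
tRNA-Trp	TRNA	-	68	7
tRNA-Gln	TRNA	-	68	8
tRNA-Gly	TRNA	-	67	5
tRNA-Glu	TRNA	-	67	-2
12S	RRNA	+	950	6
tRNA-Val	TRNA	+	69	3
16S	RRNA	+	1417	8
tRNA-Leu(TAG)	TRNA	+	67	9
tRNA-Leu(TAA)	TRNA	+	68	7
NAD1	PCG	+	939	12	ATG	TAG
tRNA-Pro	TRNA	+	67	6
NAD6	PCG	+	501	9	ATG	TAG
CYTB	PCG	+	1140	11	ATG	TAA
tRNA-Ser(TGA)	TRNA	+	68	8
tRNA-Thr	TRNA	-	68	-2
NAD4L	PCG	+	297	7	ATG	TAG
NAD4	PCG	+	1380	10	GTG	TAA
tRNA-His	TRNA	+	67	9
NAD5	PCG	+	1728	13	ATG	TAA
tRNA-Phe	TRNA	+	68	54
COX3	PCG	+	780	41	ATG	TAA
tRNA-Lys	TRNA	+	69	6
tRNA-Ala	TRNA	+	68	8
tRNA-Arg	TRNA	+	67	5
tRNA-Asn	TRNA	+	68	7
tRNA-Ile	TRNA	+	67	9
NAD3	PCG	+	354	6	ATG	TAG
tRNA-Ser(GCT)	TRNA	+	68	10
NAD2	PCG	+	1056	22	ATG	TAA
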