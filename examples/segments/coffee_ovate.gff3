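##gff-version 3
# Synthetic fixture: a coffee-like BAC segment around a fruit-shape locus.
# 16 predicted genes, family labels as an ortholog table would supply them.
coffee_bac	fixture	gene	1000	2000	.	+	.	ID=cg01;family=f01
coffee_bac	fixture	gene	3000	4000	.	+	.	ID=cg02;family=f02
coffee_bac	fixture	gene	5000	6000	.	+	.	ID=cg03;family=f03
coffee_bac	fixture	gene	7000	8000	.	+	.	ID=cg04;family=f04
coffee_bac	fixture	gene	9000	10000	.	+	.	ID=cg05;family=f05
coffee_bac	fixture	gene	11000	12000	.	+	.	ID=cg06;family=f06
coffee_bac	fixture	gene	13000	14000	.	+	.	ID=cg07;family=f07
coffee_bac	fixture	gene	15000	16000	.	+	.	ID=cg08;family=f08
coffee_bac	fixture	gene	17000	18000	.	+	.	ID=cg09;family=f09
coffee_bac	fixture	gene	19000	20000	.	+	.	ID=cg10;family=f10
coffee_bac	fixture	gene	21000	22000	.	+	.	ID=cg11;family=f11
coffee_bac	fixture	gene	23000	24000	.	+	.	ID=cg12;family=f12
coffee_bac	fixture	gene	25000	26000	.	+	.	ID=cg13;family=f13
coffee_bac	fixture	gene	27000	28000	.	+	.	ID=cg14;family=f14
coffee_bac	fixture	gene	29000	30000	.	+	.	ID=cg15;family=f15
coffee_bac	fixture	gene	31000	32000	.	+	.	ID=cg16;family=f16
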