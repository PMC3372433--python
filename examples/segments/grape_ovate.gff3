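##gff-version 3
# Synthetic fixture: a grapevine-like chromosome segment orthologous to the
# coffee fixture.  13 shared families in conserved order, one local
# orientation flip (f04), two grapevine-specific genes without a family.
grape_seg	fixture	gene	1000	2000	.	+	.	ID=gg01;family=f01
grape_seg	fixture	gene	3000	4000	.	+	.	ID=gg02;family=f02
grape_seg	fixture	gene	5000	6000	.	+	.	ID=gg03;family=f03
grape_seg	fixture	gene	7000	8000	.	-	.	ID=gg04;family=f04
grape_seg	fixture	gene	9000	10000	.	+	.	ID=gg05;family=f05
grape_seg	fixture	gene	11000	12000	.	+	.	ID=gg06;family=f06
grape_seg	fixture	gene	13000	14000	.	+	.	ID=gg07;family=f07
grape_seg	fixture	gene	15000	16000	.	+	.	ID=gg08
grape_seg	fixture	gene	17000	18000	.	+	.	ID=gg09;family=f09
grape_seg	fixture	gene	19000	20000	.	+	.	ID=gg10;family=f10
grape_seg	fixture	gene	21000	22000	.	+	.	ID=gg11;family=f11
grape_seg	fixture	gene	23000	24000	.	+	.	ID=gg12;family=f12
grape_seg	fixture	gene	25000	26000	.	+	.	ID=gg13;family=f14
grape_seg	fixture	gene	27000	28000	.	+	.	ID=gg14;family=f15
grape_seg	fixture	gene	29000	30000	.	+	.	ID=gg15
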