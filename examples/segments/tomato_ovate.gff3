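##gff-version 3
# Synthetic fixture: a tomato-like segment orthologous to the coffee
# fixture.  10 shared families, two with flipped orientation (f05, f06),
# two families present here but absent from the coffee fixture (f17, f18).
tomato_seg	fixture	gene	1000	2000	.	+	.	ID=tg01;family=f01
tomato_seg	fixture	gene	3000	4000	.	+	.	ID=tg02;family=f02
tomato_seg	fixture	gene	5000	6000	.	-	.	ID=tg03;family=f05
tomato_seg	fixture	gene	7000	8000	.	-	.	ID=tg04;family=f06
tomato_seg	fixture	gene	9000	10000	.	+	.	ID=tg05;family=f07
tomato_seg	fixture	gene	11000	12000	.	+	.	ID=tg06;family=f17
tomato_seg	fixture	gene	13000	14000	.	+	.	ID=tg07;family=f18
tomato_seg	fixture	gene	15000	16000	.	+	.	ID=tg08;family=f09
tomato_seg	fixture	gene	17000	18000	.	+	.	ID=tg09;family=f11
tomato_seg	fixture	gene	19000	20000	.	+	.	ID=tg10;family=f12
tomato_seg	fixture	gene	21000	22000	.	+	.	ID=tg11;family=f15
tomato_seg	fixture	gene	23000	24000	.	+	.	ID=tg12;family=f16
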