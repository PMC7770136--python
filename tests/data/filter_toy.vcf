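##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chrX,length=1000000>
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	T01	T02	T03	T04	T05	T06	T07	T08	T09	T10
chr1	1000	.	A	G	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	2000	.	C	T	100	.	QD=1.9;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	3000	.	G	A	100	.	QD=1.5;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	4000	.	T	C	20	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	5000	.	A	C,T	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/2:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chrX	6000	.	G	T	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	7000	.	C	G	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	8000	.	T	A	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:1	0/0:1	0/0:1	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	9000	.	A	T	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	10000	.	G	C	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	11000	.	C	A	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
chr1	12000	.	T	G	100	.	QD=25.0;FS=1.0;MQ=60.0;ReadPosRankSum=0.5;SB=-3.0	GT:DP	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
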