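code	location	lon_dms	lat_dms	altitude_m	n	haplotypes	h
HBH	Habahe, Xinjiang	86°24′	48°04′	535	9	A,B	0.556
QH1	Qinghe, Xinjiang	90°22′	46°39′	1210	8	A	0.000
QH2	Qinghe, Xinjiang	90°24′	46°40′	1211	8	A	0.000
HY	Huangyuan, Qinghai	101°02′	36°52′	2979	8	D	0.000
HB	Haibei, Qinghai	100°43′	36°56′	3048	5	D	0.000
QHH	Qinghaihu, Qinghai	100°21′	36°42′	3100	6	A,D,F	0.733
MZGK1	Mozhugongka, Xizang	91°52′	29°46′	3895	7	A	0.000
DLDQ1	Duilongdeqing, Xizang	90°45′	29°50′	3794	9	C	0.000
DX	Dangxiong, Xizang	91°06′	30°29′	4724	10	A,E	0.200
DZ	Dazi, Xizang	91°26′	29°42′	3677	8	A	0.000
DQ	Deqing, Xizang	90°56′	30°23′	4176	7	A	0.000
RKZ1	Rikaze, Xizang	88°54′	29°16′	3816	6	D	0.000
MZGK2	Mozhugongka, Xizang	91°39′	29°48′	3740	8	A	0.000
LZ	Linzhou, Xizang	91°19′	29°53′	3712	7	A,D,E	0.714
DLDQ2	Duilongdeqing, Xizang	91°01′	29°39′	3642	7	D	0.000
MX	Maxiong, Xizang	84°09′	29°41′	4540	9	A,E	0.222
RKZ2	Rikaze, Xizang	89°24′	28°20′	4446	8	A	0.000
SQ	Shaqu, Xizang	85°14′	29°25′	4679	8	A	0.000
RJ	Rujiao, Xizang	84°54′	29°34′	4578	8	A	0.000
DGL	Donggala, Xizang	89°23′	28°14′	4466	8	D	0.000
KS	Kunsha, Xizang	80°02′	32°13′	4233	6	A,E,G	0.733
BGC	Bangongcuo, Xizang	79°49′	33°27′	4266	8	A	0.000
RIS	Risong, Xizang	79°50′	33°10′	4307	8	A	0.000
RES	Resuo, Xizang	89°28′	29°01′	3951	8	C	0.000
RT	Ritu, Xizang	79°49′	32°59′	4342	11	A,B	0.327
LL	Lulong, Xizang	87°25′	29°13′	4299	8	C	0.000
AR	Angren, Xizang	86°40′	29°26′	4557	8	D	0.000
XDQ	Xinduqiao, Sichuan	101°32′	30°01′	3464	8	A	0.000
WXH	Wuxuhai, Sichuan	101°24′	29°10′	3706	8	E	0.000
LT1	Litang, Sichuan	100°23′	30°01′	4019	16	A	0.000
KD	Kangding, Sichuan	101°33′	29°50′	3353	8	A	0.000
MGC	Mugecuo, Sichuan	101°52′	30°11′	2600	6	A,D	0.533
LZG	Luozigu, Sichuan	100°09′	30°01′	3960	6	A,D	0.533
LT2	Litang, Sichuan	100°23′	29°41′	3671	8	A	0.000
DC1	Daocheng, Sichuan	100°05′	29°14′	3987	8	D	0.000
DC2	Daocheng, Sichuan	100°05′	29°17′	4089	16	D	0.000
HZS	Haizishan, Sichuan	100°11′	29°26′	4649	8	D	0.000
XC	Xiangcheng, Sichuan	100°03′	29°08′	4614	8	A	0.000
GZ1	Ganzi, Sichuan	99°55′	31°22′	4243	6	A,D	0.333
GZ2	Ganzi, Sichuan	99°55′	31°21′	4281	8	D	0.000
GZ3	Ganzi, Sichuan	99°55′	31°20′	4118	8	D	0.000
GZ4	Ganzi, Sichuan	99°38′	31°02′	3982	6	A,E	0.333
GZ5	Ganzi, Sichuan	99°24′	31°08′	3995	8	H	0.000
GZ6	Ganzi, Sichuan	99°40′	31°38′	3908	16	A	0.000
LH	Luhuo, Sichuan	100°16′	31°39′	3502	8	A	0.000
HY1	Hongyuan, Sichuan	102°20′	32°35′	3529	8	D	0.000
HY2	Hongyuan, Sichuan	102°37′	33°10′	3466	6	A,D	0.333
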