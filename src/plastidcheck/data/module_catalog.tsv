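# Synthetic test catalog of KEGG-style module DEFINITION strings.
# Hand-written for offline testing: K-numbers are drawn from plastid- and
# organelle-relevant families but the step structures are this package's
# own fixtures, not copies of the KEGG database.
module_id	definition
MX00001	K02703 K02704 K02705 K02706
MX00002	K02707+K02708 (K02709,K02710)
MX00003	K02689+K02690 K02691 K02692 K02693
MX00004	(K02694,K02696) K02697-K02698
MX00005	K02634+K02635 K02636 K02637 K02640
MX00006	K02111+K02112+K02113+K02114
MX00007	K02108+K02109+K02110 K02115
MX00008	K01601+K01602
MX00009	K00855 (K01086,K11532) K00615 K01100
MX00010	K03040+K03043 K03046 K03060
MX00011	K02945 K02967 K02982 K02986 K02992
MX00012	K02863 K02886 K02906 K02926 K02931
MX00013	(K05572,K05573) K05574+K05575 K05576
MX00014	K03403+K03404+K03405 K04035 K04037
MX00015	K02291 (K06443,K09835) K09844
MX00016	K01662 (K05588,K12506)
MX00017	K03541 K03542+K03543
MX00018	K02600,K02601 K02602
MX00019	K03689 K03690-K03691 K03692
MX00020	(K04040 K04041) K04042
MX00021	K05350,K05349
MX00022	K06960 K07374 (K08901,K08902,K08903)
MX00023	K09667+K09668-K09669
MX00024	K10793 K10794 K10795 K10796
MX00025	(K11517,K11518) (K11519,K11520)
MX00026	K12502 K12503+K12504 K12505
MX00027	K13600 K13601
MX00028	K14454 K14455 (K14456,K14457)
MX00029	K15562+K15563
MX00030	K16052 K16053 K16054-K16055
MX00031	K17054 (K17055,K17056) K17057
MX00032	K18131 K18132
MX00033	K00234+K00235+K00236+K00237
MX00034	K00411+K00412 K00413
MX00035	K19054 K19055 K19056
MX00036	K20712 (K20713,K20714) K20715+K20716
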