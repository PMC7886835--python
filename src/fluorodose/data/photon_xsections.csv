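material,energy_keV,mu_rho,mutr_rho,f_pe,f_co,f_ra
air,5,40.27,39.31,0.9771930070006015,0.004871348475054286,0.017935644524344114
air,6,23.41,22.7,0.9698320167191143,0.008348079243616472,0.021819904037269144
air,8,9.921,9.446,0.9506418593012622,0.01955135118337718,0.029806789515360647
air,10,5.12,4.742,0.9245967352886253,0.03760501718684255,0.037798247524532154
air,15,1.614,1.334,0.8273548140791129,0.1171487998071736,0.05549638611371345
air,20,0.7779,0.5389,0.6945197689102687,0.23882091364175634,0.06665931744797504
air,30,0.3538,0.1537,0.4244822891689951,0.5076827758394843,0.06783493499152063
air,40,0.2485,0.06833,0.24396845701410447,0.7001200294204055,0.05591151356549001
air,50,0.208,0.04098,0.14474711588031083,0.8115374009858107,0.043715483133878436
air,60,0.1875,0.03041,0.09090961368639824,0.8747936355124404,0.03429675080116138
air,80,0.1662,0.02407,0.04194497409919977,0.9356554585005326,0.022399567400267672
air,100,0.1541,0.02325,0.022932985808198997,0.9612567551023015,0.01581025908949954
air,150,0.1356,0.02496,0.008230378094760578,0.9834537355824924,0.008315886322747039
lung,5,43.06,42.3,0.9768048692311961,0.005023801490008019,0.01817132927879584
lung,6,24.97,24.33,0.9692078865520994,0.008630681744315945,0.022161431703584696
lung,8,10.57,10.08,0.9494555819769318,0.020236383773899164,0.0303080342491691
lung,10,5.362,4.957,0.9213027729602008,0.03959721219408153,0.03910001484571771
lung,15,1.691,1.393,0.8193135991273083,0.1233029407190383,0.05738346015365344
lung,20,0.8198,0.5652,0.6815779788911951,0.24989863333575693,0.06852338777304802
lung,30,0.378,0.1606,0.4072135056127996,0.5240034256041316,0.06878306878306878
lung,40,0.2684,0.07179,0.2291077414715916,0.714812357704602,0.056079900823806345
lung,50,0.2261,0.04341,0.13315385711826588,0.8232788915202395,0.043567251361494655
lung,60,0.2047,0.03253,0.08234881342773598,0.8836183213720398,0.034032865200224256
lung,80,0.1822,0.02612,0.03668132712545749,0.9411834252871759,0.0221352475873666
lung,100,0.1693,0.02542,0.019557860780405317,0.9648521155761637,0.015590023643431001
lung,150,0.1492,0.02743,0.006167431078937835,0.9856448765563736,0.008187692364688604
soft_tissue,5,43.11,42.37,0.9768365116239546,0.005013234635731144,0.018150253740314287
soft_tissue,6,25,24.38,0.9692529801069871,0.008612181907472519,0.022134837985540393
soft_tissue,8,10.58,10.1,0.9495224533590388,0.020198158926999193,0.030279387713961943
soft_tissue,10,5.367,4.964,0.9214134586774679,0.03952295279956987,0.039063588522962246
soft_tissue,15,1.693,1.396,0.819643388357634,0.12304094057335961,0.05731567106900648
soft_tissue,20,0.8205,0.5663,0.6820854973104921,0.24944957484509023,0.06846492784441774
soft_tissue,30,0.3783,0.161,0.40817819488792273,0.5230932827753075,0.06872852233676975
soft_tissue,40,0.2685,0.07192,0.23006983399708947,0.7138711515481261,0.056059014454784444
soft_tissue,50,0.2262,0.04349,0.13431442847195033,0.8221375806667148,0.04354799086133484
soft_tissue,60,0.2048,0.03258,0.08363117023096203,0.8823525821787748,0.034016247590263206
soft_tissue,80,0.1823,0.02615,0.038098334604909904,0.9397785600170419,0.022123105378048243
soft_tissue,100,0.1693,0.02544,0.020469289170355048,0.963940687186214,0.015590023643431001
soft_tissue,150,0.1492,0.02745,0.007098500937623464,0.9847138066976879,0.008187692364688604
bone,5,189.8,185.2,0.9846638450870707,0.0010658360576472632,0.014270318855281957
bone,6,114.9,111.8,0.9815748763279839,0.0017539763641678504,0.016671147307848258
bone,8,52.36,50.24,0.9750009345660356,0.003820220028462033,0.021178845405502262
bone,10,28.51,26.8,0.9675805995529021,0.006964249536153667,0.025455150910944135
bone,15,9.032,8.388,0.9412228672388644,0.02158804098154627,0.03718909177958931
bone,20,4.001,3.601,0.9035155381216492,0.0478832218357554,0.048601240042595396
bone,30,1.331,1.07,0.7932173192836186,0.13916434863523938,0.067618332081142
bone,40,0.6655,0.4507,0.6521174120368552,0.26959176646976984,0.07829082149337492
bone,50,0.4242,0.2336,0.5092655031745509,0.41035242034165564,0.08038207648379345
bone,60,0.3148,0.14,0.38608236846942556,0.5373137468194353,0.07660388471113912
bone,80,0.2229,0.06896,0.2179317617487816,0.7194368771825023,0.06263136106871614
bone,100,0.1855,0.04585,0.1272657853118246,0.8234816353278275,0.04925257936034795
bone,150,0.148,0.03183,0.04223140558585615,0.9291967822849758,0.028571812129168032
water,5,42.58,41.88,0.9765008467408813,0.005122980437490048,0.018376172821628674
water,6,24.64,24.05,0.9687222464438774,0.008819516963650558,0.02245823659247199
water,8,10.37,9.915,0.9483080237060038,0.0207994090795587,0.03089256721443755
water,10,5.329,4.944,0.9204817771895208,0.040176079893845924,0.03934214291663321
water,15,1.673,1.374,0.8163258617649908,0.12567328281371334,0.058000855421295856
water,20,0.8096,0.5503,0.675447093989758,0.25516620480428254,0.06938670120595944
water,30,0.3756,0.1557,0.39900942073542756,0.5317680020547748,0.06922257720979766
water,40,0.2683,0.06947,0.22283198268453278,0.7210672145532249,0.05610080276224236
water,50,0.2269,0.04223,0.12933991968369268,0.8272464375977796,0.043413642718527726
water,60,0.2059,0.0319,0.08034020743448692,0.8858252733499429,0.03383451921557021
water,80,0.1837,0.02597,0.036729703829561394,0.9413157936640794,0.02195450250635925
water,100,0.1707,0.02546,0.0195850860920464,0.9649527522041875,0.015462161703766074
water,150,0.1505,0.02764,0.0065690384766926655,0.9853139934116028,0.008116968111704584
copper,5,189.9,139.1,0.8881226967082531,0.0009443816889875703,0.11093292160275939
copper,6,118,92.66,0.8722278846828438,0.001514075960260191,0.12625803935689597
copper,8,52.55,43.83,0.8324967888688313,0.003374436038142112,0.16412877509302656
copper,8.975,38.29,32.4,0.8143443249083206,0.004614404534784612,0.18104127055689473
copper,8.985,278.4,145.7,0.9745183268826995,0.0006346228670508152,0.024847050250249712
copper,10,215.9,148.4,0.9730404981705195,0.0008152762759982781,0.026144225553482177
copper,15,74.05,57.88,0.9623855797034641,0.002334307179681667,0.0352801131168543
copper,20,33.79,27.88,0.9502143905231759,0.005026314160229092,0.04475929531659496
copper,30,10.92,9.349,0.9208601549385922,0.015037280958843706,0.0641025641025641
copper,40,4.862,4.163,0.883937777845178,0.03271339635682229,0.08334882579799968
copper,50,2.613,2.192,0.8394473048497519,0.059057377758158794,0.10149531739208924
copper,60,1.593,1.29,0.7881286346903681,0.0941310288728138,0.11774033643681814
copper,80,0.763,0.5581,0.6713688241875683,0.18632199760430915,0.14230917820812258
copper,100,0.4584,0.3148,0.549561918445375,0.29541947989811007,0.15501860165651496
copper,150,0.2217,0.1304,0.30174191140777673,0.5499074778278366,0.14835061076438671
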