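# kicksense-features v1
# S=8 L=8
# seed=
sample_id,row,SA,LA,SG,LG,class_label,intensity_label,provenance,subject_id
0,0,4.36188009882278e-06,10062.29815414023,2.4060227857982008e-05,1050085.7006103469,arch_shot,5.0,original,S01
0,1,3.220316688318718e-05,7798.811327777877,2.4060227857982265e-05,385725.0756262591,arch_shot,5.0,original,S01
0,2,3.220316688320736e-05,7600.837128346121,3.69365327748432e-05,385725.0756262591,arch_shot,5.0,original,S01
0,3,0.00039199685056387495,7303.925942496476,8.25446322880269e-05,165980.50107768076,arch_shot,5.0,original,S01
0,4,0.000425194461496759,7295.423952475591,0.0004725876971251437,147991.51723408033,arch_shot,5.0,original,S01
0,5,0.000425194461496759,7291.230949729005,0.0004725876971251437,100967.76007669246,arch_shot,5.0,original,S01
0,6,0.0005291709681510644,7262.763911153637,0.00048583706580648356,100967.76007669246,arch_shot,5.0,original,S01
0,7,0.0007242206710012282,7262.056811154538,0.00048583706580648356,99388.91722428646,arch_shot,5.0,original,S01
1,0,0.00019057483785761786,13422.693472329744,0.0002461529513648915,1620043.699912071,inside_pass,5.0,original,S01
1,1,0.00046068060945902273,7564.226008328652,0.00024615295136489205,805501.7881989249,inside_pass,5.0,original,S01
1,2,0.0004606806094591752,7503.475279031218,0.000992906524153086,805501.7881989249,inside_pass,5.0,original,S01
1,3,0.0008512274442626833,7364.81293525935,0.000992906524153086,310298.7576618566,inside_pass,5.0,original,S01
1,4,0.000851227444262813,7344.506577524501,0.00177795509182526,310298.7576618566,inside_pass,5.0,original,S01
1,5,0.0009846717095060213,7341.084935885256,0.0018186644557318422,298940.0032931539,inside_pass,5.0,original,S01
1,6,0.0009846717095060213,7329.079518632104,0.0018855043297816624,274339.92409052345,inside_pass,5.0,original,S01
1,7,0.00133230460841541,7305.5882977771935,0.0018855043297816654,83548.46194169902,inside_pass,5.0,original,S01
2,0,0.0002250730930528537,11247.765336252416,8.534160816301519e-06,1498563.2936779752,arch_shot,6.0,original,S01
2,1,0.0002996256841586607,8095.467083913628,8.534160816301626e-06,536200.0774274688,arch_shot,6.0,original,S01
2,2,0.00039919884202851665,7904.5712670388075,0.00035561291522413676,536200.0774274688,arch_shot,6.0,original,S01
2,3,0.0003991988420285724,7333.036074158224,0.00036943385148863195,237122.01192045625,arch_shot,6.0,original,S01
2,4,0.00043203730733329116,7323.968132483937,0.00036943385148863303,211511.79408776213,arch_shot,6.0,original,S01
2,5,0.00043203730733352074,7322.584515557604,0.0004283183561417111,205093.71069332698,arch_shot,6.0,original,S01
2,6,0.0004521991935917609,7306.651625639548,0.00042831835614171184,205093.71069332698,arch_shot,6.0,original,S01
2,7,0.0004521991935917609,7301.213783066209,0.0008358050987935604,148565.1929126564,arch_shot,6.0,original,S01
3,0,0.0006249708586365294,9693.80454845111,2.7307867828493947e-05,712590.2391409709,inside_pass,4.0,original,S01
3,1,0.0006424198599924425,7625.7033487287645,5.117641360761483e-05,256693.6170239866,inside_pass,4.0,original,S01
3,2,0.002014957177027384,7474.590179093428,5.1176413607615116e-05,256693.6170239866,inside_pass,4.0,original,S01
3,3,0.002014957177027454,7367.803706355041,0.00018790397541949768,149028.85142040995,inside_pass,4.0,original,S01
3,4,0.0024679478689828486,7319.103429325183,0.0002516014216272479,136854.74645349578,inside_pass,4.0,original,S01
3,5,0.0024679478689831245,7318.6926937618555,0.0002516014216272479,86335.58978211813,inside_pass,4.0,original,S01
3,6,0.003293770952019872,7311.149793583644,0.00031990674213819596,86335.58978211813,inside_pass,4.0,original,S01
3,7,0.00362438071133636,7303.264538966276,0.00031990674213819596,56557.07728539258,inside_pass,4.0,original,S01
4,0,5.238646747901572e-05,9038.502942581776,0.00040231182932583986,667896.9891425248,arch_shot,4.0,original,S02
4,1,5.238646747901572e-05,7468.992661840537,0.00040231182932583986,231540.03158412932,arch_shot,4.0,original,S02
4,2,0.00010042793848541985,7429.648049813766,0.0008541641541775841,231540.03158412932,arch_shot,4.0,original,S02
4,3,0.00013325976327381543,7272.141283508116,0.0008541641541775841,108106.94897382305,arch_shot,4.0,original,S02
4,4,0.00013325976327381624,7257.959667373632,0.0010041770172577956,101618.79968437225,arch_shot,4.0,original,S02
4,5,0.0003126403193115041,7236.1791577417125,0.0010041770172577956,101618.79968437225,arch_shot,4.0,original,S02
4,6,0.0003126403193115041,7235.454192658064,0.0015245941231656302,96759.6043341753,arch_shot,4.0,original,S02
4,7,0.00057974900601566,7194.445451695722,0.0015245941231656302,93213.35650496457,arch_shot,4.0,original,S02
5,0,0.00010793485305836962,10705.528460124946,2.0090711790762886e-06,1016992.2421630736,arch_shot,6.0,original,S02
5,1,0.00010793485305840739,7865.355280798817,2.0090711790762886e-06,710371.4481022963,arch_shot,6.0,original,S02
5,2,0.0007721276433067846,7747.1631252193765,9.713810750847737e-06,352385.5071947793,arch_shot,6.0,original,S02
5,3,0.0009633018533018993,7281.881888684236,7.884150291764065e-05,352385.5071947793,arch_shot,6.0,original,S02
5,4,0.0009633018533020731,7270.9692107207475,7.884150291764065e-05,302707.0443656793,arch_shot,6.0,original,S02
5,5,0.001027143525180145,7264.482097411479,0.00018893253396257947,302707.0443656793,arch_shot,6.0,original,S02
5,6,0.001027143525180145,7205.649424264693,0.0006479902406322242,199672.87882113623,arch_shot,6.0,original,S02
5,7,0.0014858356226774528,7151.664355400921,0.0006790328683722672,177368.49721682194,arch_shot,6.0,original,S02
6,0,1.706565639313506e-05,10356.950665674573,5.0687720527462525e-06,1000468.1817966694,inside_pass,4.0,original,S02
6,1,3.4398592154865146e-05,7548.710733042716,0.00019052334642472458,364023.0875714224,inside_pass,4.0,original,S02
6,2,0.00017738366392627282,7523.567324980996,0.00019052334642472458,364023.0875714223,inside_pass,4.0,original,S02
6,3,0.0001773836639262893,7307.403068528199,0.001393952585801982,205621.32867200236,inside_pass,4.0,original,S02
6,4,0.00019810128468930103,7251.242542758821,0.001393952585801982,189063.66479896184,inside_pass,4.0,original,S02
6,5,0.0009751029906843088,7217.60760690491,0.0014840551503493811,123852.93552685832,inside_pass,4.0,original,S02
6,6,0.0009751029906843088,7210.861979252207,0.0014840551503493829,123852.93552685827,inside_pass,4.0,original,S02
6,7,0.001079332426465637,7193.355569757595,0.001663980873474654,86341.33260781897,inside_pass,4.0,original,S02
7,0,0.00012872102214213005,9524.644442684244,3.930420961902187e-06,560239.6045068116,inside_pass,3.0,original,S02
7,1,0.00012872102214213005,7238.963713046085,1.1248559969313026e-05,241816.53108086096,inside_pass,3.0,original,S02
7,2,0.00042734812863762776,7222.690383683831,0.0014940799431622455,241816.5310808609,inside_pass,3.0,original,S02
7,3,0.00042734812863767324,7222.534786663783,0.0014940799431622455,110545.84257640783,inside_pass,3.0,original,S02
7,4,0.0004285841433946593,7220.6774912009905,0.0024830492503191215,100912.75422462574,inside_pass,3.0,original,S02
7,5,0.0004285841433946593,7188.168525497021,0.0035610228725943527,96818.22069664502,inside_pass,3.0,original,S02
7,6,0.0005579640389482995,7158.990771225671,0.0035610228725943575,96818.22069664502,inside_pass,3.0,original,S02
7,7,0.0009534649461583578,7104.615564007001,0.0040796126989024566,53176.27043149721,inside_pass,3.0,original,S02
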