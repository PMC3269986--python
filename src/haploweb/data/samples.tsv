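sample	location	coordinates	depth_m
04Oki115	Okinawa	26°12'10"N, 127°19'12"E	n.r.
04Oki136	Okinawa	26°12'10"N, 127°19'12"E	n.r.
04Oki140	Okinawa	26°12'10"N, 127°19'12"E	n.r.
04Oki195	Okinawa	26°14'25"N, 127°27'50"E	n.r.
04NC009	New Caledonia	22°26'54"S, 166°22'23"E	2
04NC012	New Caledonia	22°26'54"S, 166°22'23"E	6
04NC024	New Caledonia	22°26'54"S, 166°22'23"E	1
04NC064	New Caledonia	22°38'30"S, 166°34'40"E	16
04NC071	New Caledonia	22°40'54"S, 168°36'24"E	1
04NC087	New Caledonia	22°37'20"S, 166°36'53"E	5
04NC101	New Caledonia	22°37'20"S, 166°36'53"E	9
04NC105	New Caledonia	22°01'01"S, 165°55'10"E	26
04NC130	New Caledonia	22°22'59"S, 167°05'50"E	1
04NC131	New Caledonia	22°22'59"S, 167°05'50"E	1
04NC132	New Caledonia	22°22'59"S, 167°05'50"E	1
04NC139	New Caledonia	22°22'59"S, 167°05'50"E	1
04NC140	New Caledonia	22°22'59"S, 167°05'50"E	1
04NC141	New Caledonia	22°22'59"S, 167°05'50"E	1
04NC145	New Caledonia	22°22'59"S, 167°05'50"E	1
04NC149	New Caledonia	22°15'27"S, 166°24'33"E	16
04NC152	New Caledonia	22°15'27"S, 166°24'33"E	16
04NC170	New Caledonia	22°15'27"S, 166°24'33"E	15
04NC182	New Caledonia	22°12'31"S, 166°24'55"E	4
04NC187	New Caledonia	22°12'31"S, 166°24'55"E	4
04NC189	New Caledonia	22°12'31"S, 166°24'55"E	4
04NC199	New Caledonia	22°18'40"S, 166°27'26"E	1
04NC230	New Caledonia	20°46'18"S, 165°16'30"E	14
04NC232	New Caledonia	20°46'18"S, 165°16'30"E	13
04NC233	New Caledonia	20°46'18"S, 165°16'30"E	9
04NC237	New Caledonia	20°46'18"S, 165°16'30"E	7
04NC251	New Caledonia	20°34'59"S, 165°08'11"E	21
04NC253	New Caledonia	20°34'59"S, 165°08'11"E	19
04NC266	New Caledonia	20°34'59"S, 165°08'11"E	7
04NC282	New Caledonia	20°34'59"S, 165°08'11"E	6
04NC289	New Caledonia	20°34'59"S, 165°08'11"E	2
04NC323	New Caledonia	20°42'39"S, 165°09'14"E	6
04NC324	New Caledonia	20°42'39"S, 165°09'14"E	6
04NC336	New Caledonia	20°35'42"S, 165°10'40"E	26
04NC365	New Caledonia	20°40'12"S, 164°11'19"E	22
04NC373	New Caledonia	20°40'12"S, 164°11'19"E	15
04NC379	New Caledonia	20°40'12"S, 164°11'19"E	14
04NC404	New Caledonia	20°40'20"S, 164°14'53"E	4
04NC434	New Caledonia	20°39'58"S, 164°15'26"E	25
04NC436	New Caledonia	20°41'39"S, 164°14'50"E	24
04NC439	New Caledonia	20°41'39"S, 164°14'50"E	23
04NC440	New Caledonia	20°41'39"S, 164°14'50"E	23
04NC441	New Caledonia	20°41'39"S, 164°14'50"E	21
04NC452	New Caledonia	20°41'39"S, 164°14'50"E	1
04NC455	New Caledonia	20°41'39"S, 164°14'50"E	1
05Phil19	Philippines	16°23'46"N, 119°54'03"E	24
05Phil53	Philippines	16°26'22"N, 119°56'33"E	13
07Mad070	Madagascar	23°25'01"S, 43°38'36"E	8
07Mad071	Madagascar	23°25'01"S, 43°38'36"E	7
07Mad073	Madagascar	23°25'01"S, 43°38'36"E	5
07Mad074	Madagascar	23°25'01"S, 43°38'36"E	5
07Mad079	Madagascar	23°25'01"S, 43°38'36"E	8
07Mad082	Madagascar	23°23'07"S, 43°38'18"E	8
07Mad086	Madagascar	23°23'07"S, 43°38'18"E	6
07Mad087	Madagascar	23°30'20"S, 43°41'10"E	30
07Mad088	Madagascar	23°30'20"S, 43°41'10"E	30
07Mad150	Madagascar	23°23'29"S, 43°37'38"E	8
07Mad151	Madagascar	23°23'29"S, 43°37'38"E	8
07Mad157	Madagascar	23°23'29"S, 43°37'38"E	7
07Mad159	Madagascar	23°23'29"S, 43°37'38"E	3
07Mad160	Madagascar	23°23'29"S, 43°37'38"E	3
07Mad161	Madagascar	23°23'29"S, 43°37'38"E	2
07Mad170	Madagascar	23°22'58"S, 43°38'11"E	11
07Mad172	Madagascar	23°22'58"S, 43°38'11"E	11
07Mad188	Madagascar	23°22'58"S, 43°38'11"E	5
07Mad189	Madagascar	23°22'58"S, 43°38'11"E	3
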