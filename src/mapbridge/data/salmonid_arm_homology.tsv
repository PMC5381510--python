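arm	lake_whitefish	atlantic_salmon	brook_charr	rainbow_trout	coho_salmon	chinook_salmon	pink_salmon	chum_salmon	sockeye_salmon
1.1	Cclu28	Ssa20b	BC25	Omy27	Co15b	Ots13q	Og13b	Ok18	On11a
1.2	Cclu35	Ssa09c	BC38	Omy24	Co18a	Ots14q	Og19b	Ok01a	On14b
2.1	Cclu04a?	Ssa26	BC06a	Omy06b	Co03b	Ots04q	Og04b	Ok14b	On27a
2.2	Cclu04a?	Ssa11a	BC28	Omy26	Co08b	Ots12q	Og05b	Ok02b	On28a
3.1	Cclu25	Ssa14a	BC22	Omy08b	Co30	Ots10q	Og22	Ok23	On29
3.2	Cclu26	Ssa03a	BC11	Omy28	Co27	Ots28	Og08a	Ok15	On20b
4.1	Cclu16	Ssa09b	BC33	Omy25a	Co15a	Ots08q	Og23a	Ok30a	On05a
4.2	Cclu29	Ssa05a	BC07b	Omy14b	Co19b	Ots21	Og13a	Ok04b	On06b
5.1	Cclu05a	Ssa19b	BC01a	Omy16a	Co20a	Ots24	Og11b	Ok03	On23b
5.2	Cclu15	Ssa28	BC27	Omy20	Co25	Ots25	Og07a	Ok24	On16
6.1	Cclu05b?	Ssa01b	BC01b	Omy23	Co11a	Ots01q	Og06b	Ok02a	On28b
6.2	Cclu05b?	Ssa18a	BC36	Omy01b	Co04b	Ots06q	Og08b	Ok36	On10a
7.1	Cclu13	Ssa13b	BC08b	Omy12a	Co06a	Ots09p	Og16b	Ok12	On22b
7.2	Cclu08	Ssa04b	BC09	Omy10a	Co28	Ots30	Og02b	Ok11	On10b
8.1	Cclu36	Ssa23	BC04a	Omy04a	Co10a	Ots01p	Og06a	Ok26	On17
8.2	Cclu06a	Ssa10a	BC17	Omy05b	Co13a	Ots05q	Og15a	Ok01b	On24a
9.1	Cclu06b	Ssa02b	BC42	Omy13a	Co20b	Ots32	Og26a	Ok32a	On21a
9.2	Cclu38b	Ssa12a	BC03b	Omy17b	Co01b	Ots02q	Og18a	Ok10b	On15b
10.1	Cclu10	Ssa27	BC23	Omy18b	Co17a	Ots13p	Og24a	Ok20	On04a
10.2	Cclu24a	Ssa14b	BC34	Omy14a	Co14b	Ots31	Og09b	Ok19a	On07a
11.1	Cclu18	Ssa06a	BC14	Omy13b	Co10b	Ots27	Og26b	Ok32b	On21b
11.2	-	Ssa03b	BC08a	Omy12b	Co06b	Ots09q	Og16a	Ok05	On26
12.1	Cclu27	Ssa13a	BC18	Omy16b	Co24	Ots22	Og10a	Ok27	On20a
12.2	Cclu14	Ssa15b	BC30	Omy09b	Co17b	Ots16q	Og03a	Ok28a	On07b
13.1	Cclu34	Ssa24	BC06b	Omy06a	Co03a	Ots04p	Og04a	Ok14a	On27b
13.2	Cclu37	Ssa20a	BC40	Omy11a	Co08a	Ots12p	Og05a	Ok25	On13b
14.1	Cclu04b	Ssa01c	BC13	Omy05a	Co23	Ots20	Og11a	Ok09	On04b
14.2	Cclu33	Ssa11b	BC10	Omy29	Co29	Ots33	Og20	Ok06	On19
15.1	Cclu31	Ssa09a	BC35	Omy25b	Co14a	Ots08p	Og10b	Ok35a	On12a
15.2	Cclu22	Ssa01a	BC12	Omy19b	Co07b	Ots11q	Og17a	Ok29a	On18a
16.1	Cclu02+03	Ssa21	BC26	Omy22	Co26	Ots26	Og01b	Ok07	On01
16.2	Cclu32	Ssa25	BC24	Omy03b	Co02b	Ots03q	Og09a	Ok34a	On03a
17.1	Cclu38a	Ssa12b	BC03a	Omy17a	Co01a	Ots02p	Og18b	Ok10a	On15a
17.2	Cclu21	Ssa22	BC21	Omy07b	Co05b	Ots07q	Og03b	Ok21	On02b
18.1	Cclu40	Ssa15a	BC19	Omy08a	Co12a	Ots05p	Og12a	Ok19b	On24b
18.2	Cclu17	Ssa06b	BC31	Omy04b	Co21	Ots18	Og14a	Ok08	On13a
19.1	Cclu30	Ssa10b	BC15	Omy02b	Co22	Ots19	Og01a	Ok17	On09
19.2	Cclu11	Ssa16a	BC20	Omy01a	Co04a	Ots06p	Og02a	Ok22	On25
20.1	Cclu01a?	Ssa05b	BC07a	Omy02a	Co13b	Ots23	Og15b	Ok31	On14a
20.2	Cclu01a?	Ssa02a	BC29	Omy03a	Co02a	Ots03p	Og19a	Ok34b	On03b
21.1	Cclu12	Ssa29	BC05b	Omy15a	Co11b	Ots29	Og07b	Ok04a	On06a
21.2	Cclu39	Ssa19a	BC16	Omy11b	Co18b	Ots16p	Og12b	Ok28b	On22a
22.1	Cclu19?	Ssa17a	BC39	Omy07a	Co05a	Ots07p	Og21b	Ok37	On02a
22.2	Cclu19?	Ssa16b	BC05a	Omy18a	Co16b	Ots14p	Og23b	Ok30b	On05b
23.1	Cclu02	Ssa07b	BC02b	Omy21a	Co09a	Ots15p	Og25a	Ok13b	On08b
23.2	Cclu01b	Ssa17b	BC37	Omy15b	Co19a	Ots17	Og14b	Ok33	On23a
24.1	Cclu24b	Ssa07a	BC02a	Omy21b	Co09b	Ots15q	Og25b	Ok13a	On08a
24.2	Cclu23	Ssa18b	BC32	Omy09a	Co16a	Ots10p	Og21a	Ok35b	On12b
25.1	-	Ssa04a	BC04b	Omy10b	Co12b	Ots34	Og24b	Ok16	On11b
25.2	-	Ssa08	BC41	Omy19a	Co07a	Ots11p	Og17b	Ok29b	On18b
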