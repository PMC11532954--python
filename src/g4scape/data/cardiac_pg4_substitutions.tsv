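pg4_region	pg4_strand	gene	disease	substitution	dg_arrow	tm_arrow	n_arrow
chr11:2445235-2445338	-	KCNQ1	Long QT syndrome	chr11:2445268G>T	down	down	down
chr11:2445235-2445338	-	KCNQ1	Long QT syndrome	chr11:2445270G>C	down	down	down
chr11:2445235-2445338	-	KCNQ1	Long QT syndrome	chr11:2445295C>T	down	equal	down
chr11:2445235-2445338	-	KCNQ1	Long QT syndrome	chr11:2445315C>A	equal	equal	equal
chr3:38550463-38550522	+	SCN5A	Long QT syndrome	chr3:38550499C>T	equal	equal	equal
chr3:38550463-38550522	+	SCN5A	Long QT syndrome	chr3:38550500G>A	equal	equal	up
chr3:38555638-38555702	+	SCN5A	Long QT syndrome	chr3:38555682G>T	up	down	up
chr3:38555638-38555702	+	SCN5A	Long QT syndrome	chr3:38555682G>A	up	down	equal
chr7:150946880-150946951	+	KCNH2	Long QT syndrome	chr7:150946905G>A	up	up	up
chr7:150946880-150946951	+	KCNH2	Long QT syndrome	chr7:150946929G>A	down	up	equal
chr7:150947400-150947464	+	KCNH2	Long QT syndrome	chr7:150947435G>T	equal	equal	down
chr7:150947400-150947464	+	KCNH2	Long QT syndrome	chr7:150947440G>A	equal	equal	down
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947790C>T	up	down	up
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947791C>T	up	down	down
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947798C>T	up	down	up
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947800C>T	down	down	down
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947800C>G	down	down	up
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947801C>A	equal	down	equal
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947806C>T	up	down	down
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947807G>A	up	down	equal
chr7:150947766-150947832	-	KCNH2	Long QT syndrome	chr7:150947812C>T	down	equal	up
chr7:150947803-150947867	-	KCNH2	Long QT syndrome	chr7:150947833G>A	up	down	down
chr7:150950129-150950189	-	KCNH2	Long QT syndrome	chr7:150950168C>T	equal	equal	down
chr7:150950129-150950189	-	KCNH2	Long QT syndrome	chr7:150950168C>G	equal	equal	up
chr7:150950129-150950189	-	KCNH2	Long QT syndrome	chr7:150950168C>A	equal	equal	equal
chr1:42746734-42746800	+	P3H1	Osteogenesis imperfecta	chr1:42746765G>A	up	down	up
chr17:50199219-50199296	+	COL1A1	Osteogenesis imperfecta	chr17:50199255C>A	up	down	equal
chr12:49027043-49027110	+	KMT2D	Kabuki syndrome	chr12:49027070G>A	down	up	down
chr12:49027043-49027110	+	KMT2D	Kabuki syndrome	chr12:49027073C>T	equal	equal	down
chr12:49027043-49027110	+	KMT2D	Kabuki syndrome	chr12:49027084G>T	down	up	down
chr12:49027043-49027110	+	KMT2D	Kabuki syndrome	chr12:49027088G>A	up	up	down
chr12:49031667-49031751	+	KMT2D	Kabuki syndrome	chr12:49031704G>A	down	up	equal
chr12:49038517-49038586	+	KMT2D	Kabuki syndrome	chr12:49038543G>A	equal	equal	equal
chr12:49042262-49042329	+	KMT2D	Kabuki syndrome	chr12:49042305C>A	equal	equal	equal
chr12:49053021-49053085	-	KMT2D	Kabuki syndrome	chr12:49053047C>A	up	up	down
chr12:49053021-49053085	-	KMT2D	Kabuki syndrome	chr12:49053059C>T	up	up	equal
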