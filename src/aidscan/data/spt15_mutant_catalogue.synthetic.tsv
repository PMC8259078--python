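# synthetic reconstruction of the SPT15 base-edited mutant catalogue
# nucleotide changes inferred from reported protein labels under
# single-site editing-window constraints; synonymous bystander edits
# are not recoverable and absent; ref/alt are on the edited strand
# unreachable_labels=R238R
strain_id	reported_label	cds_position	edited_strand	ref_base	alt_base
A2V	A2V	5	+	C	T
A2D	A2D	5	+	C	A
R6C	R6C	16	+	C	T
R6G	R6G	16	+	C	G
E9K	E9K	25	-	C	T
P20L	P20L	59	+	C	T
P20R	P20R	59	+	C	G
W26S	W26S	77	-	C	G
W26C	W26C	78	-	C	G
T38I	T38I	113	+	C	T
T38S	T38S	113	+	C	G
S42N	S42N	125	-	C	T
D56E	D56E	168	+	C	G
P65L	P65L	194	+	C	T
V71I	V71I	211	-	C	T
V71I	V71I	213	-	C	T
V71L	V71L	211	-	C	G
A101P/V102I	A101P/V102I	301	-	C	G
A101P/V102I	A101P/V102I	304	-	C	T
V102L	V102L	304	-	C	G
S118L	S118L	353	+	C	T
T124S	T124S	371	+	C	G
T124I	T124I	371	+	C	T
A140G	A140G	419	+	C	G
R141K	R141K	422	-	C	T
R141T	R141T	422	-	C	G
A150P	A150P	448	-	C	G
A150T	A150T	448	-	C	T
P169A	P169A	505	+	C	G
G174V	G174V	521	-	C	A
P187A	P187A	559	+	C	G
P191C	P191C	571	+	C	T
P191C	P191C	572	+	C	G
M197I	M197I	591	-	C	T
L214F	L214F	640	+	C	T
L214V	L214V	640	+	C	G
R238K	R238K	713	-	C	T
R238T	R238T	713	-	C	G
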