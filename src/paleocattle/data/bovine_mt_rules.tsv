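# Default taurine mtDNA haplogroup diagnostic rules (V00654 coordinates).
# The tree is rooted at the macro-haplogroups T, Q, P and R; T3 is the
# European default profile (no extra requirements beyond T).  Only the T/Q
# split at position 15953 is fixed by the marker design of the amplified
# fragments; the remaining diagnostic positions follow published control-
# region motifs in spirit but are placeholders meant to be replaced by a
# project-specific site list.  Format: label <TAB> parent <TAB> pos=allele[,pos=allele...]
# default_label: T3
T	-	15953=G
Q	-	15953=A
P	-	16058=T
R	-	16289=C
T1	T	16050=T,16113=T
T1f	T1	16231=C
T2	T	16057=A,16185=T
T3	T	-
T3b	T3	16255=A
T4	T3	16042=T
T5	T	13059=T
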