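base,atom,edges,role
A,N1,W-C,acceptor
A,C2,W-C|Sugar,none
A,N6,W-C|Hoogsteen,donor
A,N7,Hoogsteen,acceptor
A,C8,Hoogsteen,none
A,N3,Sugar,acceptor
A,O2',Sugar,both
G,N1,W-C,donor
G,N2,W-C|Sugar,donor
G,O6,W-C|Hoogsteen,acceptor
G,N7,Hoogsteen,acceptor
G,C8,Hoogsteen,none
G,N3,Sugar,acceptor
G,O2',Sugar,both
C,N3,W-C,acceptor
C,O2,W-C|Sugar,acceptor
C,N4,W-C|Hoogsteen,donor
C,C5,Hoogsteen,none
C,C6,Hoogsteen,none
C,O2',Sugar,both
U,N3,W-C,donor
U,O2,W-C|Sugar,acceptor
U,O4,W-C|Hoogsteen,acceptor
U,C5,Hoogsteen,none
U,C6,Hoogsteen,none
U,O2',Sugar,both
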