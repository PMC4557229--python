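class,base_i,base_j,orientation,edge_i,edge_j,bonds
I,A,A,trans,W-C,W-C,N6-N1;N1-N6
II,A,A,cis,W-C,W-C,N6-N1;N1-N6
III,G,G,trans,W-C,W-C,N1-O6;O6-N1
IV,G,G,trans,W-C,Sugar,N1-N3;O6-N2
V,A,A,trans,W-C,Hoogsteen,N6-N7;N1-N6
VI,A,A,cis,W-C,Hoogsteen,N6-N7;N1-N6
VII,G,G,trans,W-C,Hoogsteen,N1-N7;N2-O6
VIII,A,G,cis,W-C,W-C,N1-N1;N6-O6
IX,A,G,cis,W-C,Hoogsteen,N6-N7;N1-C8
X,A,G,trans,W-C,Sugar,N6-N3;N1-N2
XI,G,A,trans,Sugar,Hoogsteen,N2-N7;N3-N6
XII,U,U,trans,W-C,W-C,N3-O4;O4-N3
XIII,U,U,cis,W-C,W-C,N3-O2;O2-N3
XIV,C,C,trans,W-C,W-C,N4-N3;N3-N4
XV,C,C,cis,W-C,W-C,N4-N3;N3-N4
XVI,U,U,cis,W-C,W-C,N3-O2;O4-N3
XVII,C,U,trans,W-C,W-C,N4-O2;N3-N3
XVIII,C,U,cis,W-C,W-C,N4-O4;N3-N3
XIX,G,C,cis,W-C,W-C,N1-N3;N2-O2;O6-N4
XX,A,U,cis,W-C,W-C,N1-N3;N6-O4
XXI,A,U,trans,W-C,W-C,N1-N3;N6-O2
XXII,G,C,trans,W-C,W-C,N1-O2;N2-N3
XXIII,A,U,cis,Hoogsteen,W-C,N7-N3;N6-O4
XXIV,A,U,trans,Hoogsteen,W-C,N7-N3;N6-O2
XXV,A,C,trans,Hoogsteen,W-C,N7-N4;N6-N3
XXVI,A,C,cis,Hoogsteen,W-C,N7-N4;N6-N3
XXVII,G,U,trans,W-C,W-C,N1-O4;O6-N3
XXVIII,G,U,cis,W-C,W-C,O6-N3;N1-O2
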