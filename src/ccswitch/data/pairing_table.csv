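res_a,res_aprime,energy
I,I,-2.00
I,L,-1.70
I,V,-1.60
I,A,-1.00
I,S,-0.90
I,T,-0.70
I,N,-0.35
I,Q,-0.30
L,L,-1.55
L,V,-1.40
L,A,-0.90
L,S,-0.60
L,T,-0.50
L,N,-0.30
L,Q,-0.25
V,V,-1.30
V,A,-0.80
V,S,-0.55
V,T,-0.45
V,N,-0.28
V,Q,-0.22
A,A,-0.50
A,S,-0.45
A,T,-0.30
A,N,-0.20
A,Q,-0.18
S,S,-0.40
S,T,-0.25
S,N,-0.20
S,Q,-0.15
T,T,-0.35
T,N,-0.22
T,Q,-0.18
N,N,-0.60
N,Q,-0.25
Q,Q,-0.30
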