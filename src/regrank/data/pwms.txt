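>EBOX
A [ 5 85 5 5 5 5 ]
C [ 85 5 5 85 5 5 ]
G [ 5 5 85 5 5 85 ]
T [ 5 5 5 5 85 5 ]
>GATA
A [ 45 5 85 5 85 85 ]
C [ 5 5 5 5 5 5 ]
G [ 5 85 5 5 5 5 ]
T [ 45 5 5 85 5 5 ]
>ETS
A [ 85 5 85 5 5 85 85 5 ]
C [ 5 85 5 5 5 5 5 5 ]
G [ 5 5 5 85 85 5 5 85 ]
T [ 5 5 5 5 5 5 5 5 ]
>LEF
A [ 5 5 5 5 5 5 5 ]
C [ 85 85 5 5 5 5 5 ]
G [ 5 5 5 5 5 85 5 ]
T [ 5 5 85 85 85 5 85 ]
>SP1
A [ 5 5 5 5 5 5 5 5 5 ]
C [ 5 5 5 5 85 5 5 5 5 ]
G [ 85 85 85 85 5 85 85 85 85 ]
T [ 5 5 5 5 5 5 5 5 5 ]
>CREB
A [ 5 5 85 5 5 5 5 85 ]
C [ 5 5 5 85 5 5 85 5 ]
G [ 5 85 5 5 85 5 5 5 ]
T [ 85 5 5 5 5 85 5 5 ]
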