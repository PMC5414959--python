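accession	name	venn	nd
GO:0003824	catalytic activity	ABE	0
GO:0005488	binding	ABE	0.07
GO:0005215	transporter activity	ABE	0.14
GO:0060089	molecular transducer activity	ABE	0.21
GO:0000988	protein binding transcription factor activity	ABE	0.29
GO:0016209	antioxidant activity	ABE	0.36
GO:0009055	electron carrier activity	ABE	0.43
GO:0030234	enzyme regulator activity	ABE	0.5
GO:0005198	structural molecule activity	BE	0.57
GO:0004872	receptor activity	BE	0.64
GO:0001071	nucleic acid binding transcription factor activity	BE	0.71
GO:0016247	channel regulator activity	BE	0.86
GO:0045182	translation regulator activity	E	0.86
GO:0030545	receptor regulator activity	E	0.86
GO:0031386	protein tag	E	0.93
GO:0016530	metallochaperone activity	E	1
GO:0016015	morphogen activity	E	1
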