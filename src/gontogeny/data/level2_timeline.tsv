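accession	name	venn	nd
GO:0097159	organic cyclic compound binding	ABE	0.02
GO:1901363	heterocyclic compound binding	ABE	0.02
GO:0036094	small molecule binding	ABE	0.03
GO:0097367	carbohydrate derivative binding	ABE	0.05
GO:0016740	transferase activity	ABE	0.07
GO:0016787	hydrolase activity	ABE	0.08
GO:0016491	oxidoreductase activity	ABE	0.1
GO:0016874	ligase activity	ABE	0.12
GO:0016829	lyase activity	ABE	0.14
GO:0016853	isomerase activity	ABE	0.15
GO:0004871	signal transducer activity	ABE	0.17
GO:0022857	transmembrane transporter activity	ABE	0.19
GO:0022892	substrate-specific transporter activity	ABE	0.2
GO:0048037	cofactor binding	ABE	0.22
GO:0000990	core RNA polymerase binding transcription factor activity	ABE	0.24
GO:0008144	drug binding	ABE	0.27
GO:0033218	amide binding	ABE	0.27
GO:1901681	sulfur compound binding	ABE	0.27
GO:0019239	deaminase activity	ABE	0.31
GO:0038023	signaling receptor activity	ABE	0.31
GO:0004601	peroxidase activity	ABE	0.32
GO:0004129	cytochrome-c oxidase activity	ABE	0.32
GO:0019534	toxin transporter activity	ABE	0.34
GO:0070283	radical SAM enzyme activity	ABE	0.34
GO:0090484	drug transporter activity	ABE	0.34
GO:0004784	superoxide dismutase activity	ABE	0.36
GO:0004791	thioredoxin-disulfide reductase activity	ABE	0.39
GO:0004133	glycogen debranching enzyme activity	ABE	0.41
GO:0005515	protein binding	ABE	0.41
GO:0008430	selenium binding	ABE	0.41
GO:0008987	quinolinate synthetase A activity	ABE	0.41
GO:0060589	nucleoside-triphosphatase regulator activity	ABE	0.41
GO:0030246	carbohydrate binding	ABE	0.42
GO:0008289	lipid binding	ABE	0.44
GO:0019207	kinase regulator activity	ABE	0.46
GO:0008047	enzyme activator activity	E	0.47
GO:0004857	enzyme inhibitor activity	ABE	0.49
GO:0061134	peptidase regulator activity	ABE	0.51
GO:0060090	binding, bridging	E	0.53
GO:0003700	sequence-specific DNA binding transcription factor activity	BE	0.54
GO:0005212	structural constituent of eye lens	E	0.56
GO:0000989	transcription factor binding transcription factor activity	ABE	0.59
GO:0010576	metalloenzyme regulator activity	BE	0.59
GO:0038024	cargo receptor activity	ABE	0.59
GO:0008265	Mo-molybdopterin cofactor sulfurase activity	E	0.63
GO:0019208	phosphatase regulator activity	ABE	0.63
GO:0008307	structural constituent of muscle	E	0.64
GO:0009975	cyclase activity	ABE	0.64
GO:0030337	DNA polymerase processivity factor activity	AE	0.64
GO:0038187	pattern recognition receptor activity	E	0.66
GO:0090079	translation regulator activity, nucleic acid binding	E	0.68
GO:0019911	structural constituent of myelin sheath	E	0.69
GO:0050997	quaternary ammonium group binding	E	0.71
GO:0010851	cyclase regulator activity	E	0.73
GO:0030235	nitric-oxide synthase regulator activity	E	0.75
GO:0030546	receptor activator activity	E	0.75
GO:0015643	toxic substance binding	BE	0.76
GO:0016248	channel inhibitor activity	BE	0.78
GO:0001618	virus receptor activity	E	0.81
GO:0051183	vitamin transporter activity	E	0.81
GO:0005201	extracellular matrix structural constituent	E	0.83
GO:0005487	nucleocytoplasmic transporter activity	E	0.85
GO:0017080	sodium channel regulator activity	BE	0.85
GO:0005055	laminin receptor activity	E	0.86
GO:0005246	calcium channel regulator activity	BE	0.86
GO:0005326	neurotransmitter transporter activity	E	0.86
GO:0017056	structural constituent of nuclear pore	E	0.86
GO:0097493	structural molecule activity conferring elasticity	E	0.86
GO:0032947	protein complex scaffold	E	0.88
GO:0043028	cysteine-type endopeptidase regulator activity involved in apoptotic process	E	0.88
GO:0005549	odorant binding	E	0.9
GO:0019825	oxygen binding	E	0.9
GO:0030548	acetylcholine receptor regulator activity	E	0.9
GO:0032451	demethylase activity	ABE	0.9
GO:0042165	neurotransmitter binding	E	0.9
GO:0000386	second spliceosomal transesterification activity	E	0.92
GO:0003682	chromatin binding	E	0.92
GO:0030371	translation repressor activity	E	0.92
GO:0051184	cofactor transporter activity	ABE	0.92
GO:0008641	small protein activating enzyme activity	E	0.93
GO:0035804	structural constituent of egg coat	E	0.93
GO:0042910	xenobiotic transporter activity	ABE	0.93
GO:1901505	carbohydrate derivative transporter activity	ABE	0.93
GO:0003823	antigen binding	E	0.95
GO:0016531	copper chaperone activity	E	0.95
GO:0019808	polyamine binding	E	0.95
GO:0042562	hormone binding	E	0.95
GO:1901476	carbohydrate transporter activity	ABE	0.95
GO:0004362	glutathione-disulfide reductase activity	ABE	0.95
GO:0005200	structural constituent of cytoskeleton	BE	0.97
GO:0043021	ribonucleoprotein complex binding	BE	0.97
GO:0000035	acyl binding	E	0.98
GO:0015607	fatty-acyl-CoA transporter activity	E	0.98
GO:0030547	receptor inhibitor activity	E	0.98
GO:0001871	pattern binding	BE	1
GO:0005199	structural constituent of cell wall	BE	1
GO:0005213	structural constituent of chorion	E	1
GO:0008907	integrase activity	AB	1
GO:0009009	site-specific recombinase activity	AB	1
GO:0042979	ornithine decarboxylase regulator activity	E	1
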