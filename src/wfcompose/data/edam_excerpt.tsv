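# EDAM 1.18 excerpt covering the proteomics tool library bundled with
# wfcompose.  Concept ids printed in the underlying study (operation:3631,
# 3633, 3639, 3645, 3646, 3648, 3630, 3767, 2436; data:0943, 0945, 0928,
# 1506, 2600; format:3712, 1915) are verbatim; the remaining ids and the
# intermediate hierarchy are a reconstruction of the relevant EDAM
# neighbourhood and are internal to this fixture.
id	label	branch	parents
data:0006	Data	data
data:0928	Gene expression profile	data	data:0006
data:0943	Mass spectrum	data	data:2536
data:0945	Protein identification	data	data:0006
data:1009	Protein name	data	data:0006
data:1501	Amino acid index	data	data:0006
data:1506	Amino acid index (hydropathy)	data	data:1501
data:2536	Mass spectrometry data	data	data:0006
data:2600	Pathway or network	data	data:0006
format:1915	Format	format
format:2330	Textual format	format	format:1915
format:2332	XML	format	format:1915
format:3244	mzML	format	format:2332
format:3247	mzIdentML	format	format:2332
format:3475	TSV	format	format:1915
format:3651	MGF	format	format:1915
format:3652	MS2	format	format:1915
format:3654	mzXML	format	format:2332
format:3655	pepXML	format	format:2332
format:3711	X!Tandem XML	format	format:2332
format:3712	Thermo RAW	format	format:1915
format:3713	SearchGUI archive	format	format:1915
format:3747	protXML	format	format:2332
format:3752	CSV	format	format:1915
operation:0004	Operation	operation
operation:0335	Formatting	operation	operation:0004
operation:2423	Prediction and recognition	operation	operation:0004
operation:2436	Gene-set enrichment analysis	operation	operation:0004
operation:3630	Protein quantification	operation	operation:0004
operation:3631	Peptide identification	operation	operation:0004
operation:3633	Retention time prediction	operation	operation:2423
operation:3639	iTRAQ	operation	operation:3630
operation:3645	PTM identification	operation	operation:3631
operation:3646	Peptide database search	operation	operation:3631
operation:3648	Validation of peptide-spectrum matches	operation	operation:3631
operation:3767	Protein identification	operation	operation:0004
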