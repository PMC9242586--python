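# Autosomal ancestry block sizes (in megabase) for 31 coyotes sampled in
# southwestern Louisiana: average block size for each ancestry state per coyote.
# "joint" is the heterozygous ancestry state. Cameron parish rows carry the
# published subregion label (NW/NE/SW); other parishes have no subregion.
sample	parish	subregion	coyote_mb	joint_mb	redwolf_mb
CL12923	Cameron	NW	16.9	24.2	122.6
CL12924	Cameron	NW	9.0	25.7	122.6
CL12926	Cameron	NW	8.7	3.9	47.6
CL12927	Cameron	NW	14.9	7.8	16.0
CL12928	Cameron	NW	36.7	3.1	4.0
CL12929	Cameron	NW	9.1	26.6	87.2
CL12930	Cameron	NE	18.6	7.2	5.0
CL12931	Cameron	NE	23.5	0.7	3.1
CL12932	Cameron	NE	4.2	9.8	34.2
CL12933	Cameron	NE	0.5	0.3	32.4
CL12935	Jefferson Davis		13.6	0.7	11.4
CL12936	Jefferson Davis		6.7	8.2	23.7
CL12937	Jefferson Davis		2.3	1.5	9.1
CL12938	Jefferson Davis		30.8	46.3	8.3
CL12939	Cameron	NW	9.3	2.8	46.3
CL12940	Cameron	NW	24.9	0.4	3.6
CL12973	Cameron	SW	13.3	20.1	5.9
CL12974	Cameron	SW	20.9	1.2	2.5
CL12975	Cameron	SW	28.8	30.8	0.7
CL12976	Cameron	SW	5.1	1.1	2.8
CL12977	Cameron	SW	32.1	4.4	0.6
CL12978	Cameron	SW	10.7	8.0	5.1
CL12979	Cameron	SW	2.2	31.8	1.6
CL12980	Cameron	SW	33.6	0.6	3.1
CL12981	Jefferson Davis		7.6	16.2	7.8
CL12982	Cameron	SW	10.1	18.8	6.9
CL12983	Cameron	SW	31.4	0.2	1.0
CL13003	East Baton Rouge		13.9	11.4	6.0
CL13004	East Baton Rouge		13.9	1.6	9.4
CL13005	Iberville		15.4	13.0	10.4
CL13006	Calcasieu		26.4	1.9	2.9
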