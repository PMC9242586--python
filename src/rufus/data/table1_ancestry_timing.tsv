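# Proportion and timing (in years) of red wolf genomic ancestry for 31 coyotes
# sampled in southwestern Louisiana, as published.
# correction: CL12980 autosomal timing is printed "209." in the source table; the
# only reading consistent with the column scale (and the published Cameron-parish
# mean of 20 years) is 20.9, which is stored here. See the `corrected` column.
sample	parish	auto_ancestry	x_ancestry	auto_timing_years	x_timing_years	corrected
CL12923	Cameron	0.629	0.561	16.5	35.7	0
CL12924	Cameron	0.678	0.957	14.7	0.0	0
CL12926	Cameron	0.635	0.883	15.1	26.2	0
CL12927	Cameron	0.573	1.000	17.5	0.0	0
CL12928	Cameron	0.394	0.632	20.8	34.9	0
CL12929	Cameron	0.595	0.723	16.9	20.2	0
CL12930	Cameron	0.487	0.877	19.7	31.3	0
CL12931	Cameron	0.241	0.901	25.4	37.9	0
CL12932	Cameron	0.286	0.695	23.1	25.5	0
CL12933	Cameron	0.254	0.526	24.9	16.3	0
CL12935	Jefferson Davis	0.374	0.693	19.5	28.6	0
CL12936	Jefferson Davis	0.247	0.314	20.7	18.8	0
CL12937	Jefferson Davis	0.238	0.475	24.0	10.8	0
CL12938	Jefferson Davis	0.249	0.296	24.8	35.7	0
CL12939	Cameron	0.693	0.860	17.1	22.4	0
CL12940	Cameron	0.312	0.184	21.6	18.0	0
CL12973	Cameron	0.467	0.889	18.4	20.5	0
CL12974	Cameron	0.300	0.911	23.6	25.0	0
CL12975	Cameron	0.351	0.525	21.0	24.4	0
CL12976	Cameron	0.435	0.860	19.8	16.8	0
CL12977	Cameron	0.579	0.311	19.3	18.9	0
CL12978	Cameron	0.391	0.868	21.0	35.4	0
CL12979	Cameron	0.451	0.501	19.8	27.0	0
CL12980	Cameron	0.389	0.743	20.9	31.8	1
CL12981	Jefferson Davis	0.207	0.691	26.1	28.5	0
CL12982	Cameron	0.446	0.777	19.1	19.5	0
CL12983	Cameron	0.312	0.447	22.6	38.3	0
CL13003	East Baton Rouge	0.098	0.336	26.5	24.2	0
CL13004	East Baton Rouge	0.124	0.110	27.2	34.5	0
CL13005	Iberville	0.141	0.437	28.2	27.5	0
CL13006	Calcasieu	0.182	0.249	26.6	18.1	0
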