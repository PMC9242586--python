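# Sample information for 10 Texas canids from the 1970s red wolf capture efforts.
# Red wolf ancestry proportions are from previously published genome analyses.
# An asterisk on the sample id marks coastal-county captures, as published.
sample	county	coastal	rw_ancestry	collection_date
70-TX-01	Webb	0	0.02	1976-03-22
70-TX-02	Webb	0	0.02	1976-03-23
70-TX-03	Jefferson	1	0.11	1976-01-24
70-TX-04	Jefferson	1	0.52	1976-01-25
70-TX-05	Harris	1	0.19	1976-01-04
70-TX-06	Montague	0	0.02	1975-11-21
70-TX-07	Brazoria	1	0.03	1975-02-02
70-TX-08	Liberty	1	0.27	1975-07-31
70-TX-09	Brazoria	1	0.29	1975-05-07
70-TX-10	Webb	0	0.02	1976-03-23
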