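name	c_start	c_end	n_tl_max
trpL	27	71	0
trpE	180	1742	4
trpD	1750	3345	4
trpC	3350	4708	5
trpB	4720	5913	10
trpA	5920	6726	10
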