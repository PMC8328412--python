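location,working_days,n_photographs
100 m from the river bank,6,271
300 m from the river bank,7,270
On the side of the road,4,130
Gentle sunny slope,7,201
Steep sunny slope,6,105
Benchland of the river,5,161
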