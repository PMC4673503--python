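strain,alcohol,chain_length,titer_mg_l
KIVD_VLV,pentanol,5,118
KIVD_VLV,hexanol,6,341
KIVD_VLV,heptanol,7,269
GEO175,butanol,4,19
GEO175,pentanol,5,88
GEO175,hexanol,6,160
GEO175,heptanol,7,274
GEO175,octanol,8,10
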