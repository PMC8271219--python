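Source Target Type
ERa66 ERa36 2
ERa66 ERa66 1
ERa66 SLUG 2
SLUG ERa66 2
ZEB1 ERa66 2
ERa36 ZEB1 1
ZEB1 miR200 2
miR200 ZEB1 2
ZEB1 ZEB1 1
SLUG miR200 2
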