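>rdnE_reference_synthetic 138aa triad D39/E53/K55 [synthetic stand-in]
NMAPTTYIIFYLHHPYHAQHECQRCKFMWYSQWVVQDPDGIQENGVVRAHITEPKEGGTTFDCMNLYIYQ
LRSPQWDRAVKWAENVNCCKNPSGYVRHIHMNPMVCMQIENFDCKRNMFIKACIWRCHVDARWMEIQA
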