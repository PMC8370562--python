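word_a	word_b	relation	category
GORILLA	APE	subordinate_of	ANIMALS
RAISIN	GRAPE	same_entity_variant	FRUITS
LAMB	SHEEP	same_entity_variant	ANIMALS
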