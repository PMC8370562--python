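UTTER
OTTERS
HOTTER
POTTER
OUTER
OTHER
COTTER
BUTTER
LETTER
MATTER
MOTHER
OTTER
APPLE
APPLES
AMPLE
GRAPE
GRAPES
DRAPE
GRADE
CAT
CATS
COT
CUT
CART
DOG
DOGS
DIG
DOT
LOG
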