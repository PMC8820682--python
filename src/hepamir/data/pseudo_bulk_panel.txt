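# Synthetic pseudo-panel: union of the signature members marked overlapping
# with the study's bulk-tissue miRNA data set. A stand-in for the real
# 420-miRNA NanoString panel, sufficient only for overlap arithmetic.
let-7b
let-7c
let-7e
miR-125b-5p
miR-132
miR-143
miR-145
miR-152
miR-199a-5p
miR-21
miR-210
miR-214
miR-22
miR-221
miR-222
miR-31
miR-207
miR-335
miR-195
miR-16
miR-30a
miR-122
miR-30d
miR-30b-5p
let-7f
miR-30c
miR-194
miR-192
miR-29a
miR-26b
miR-126
miR-146a
miR-296
miR-125a-5p
miR-26a
miR-99a
miR-181a
miR-150
miR-483
miR-351
miR-146b
miR-322
miR-374
miR-10b
miR-497
miR-140
let-7i
miR-142-3p
miR-466d
miR-532-5p
miR-99b
miR-151
miR-142-5p
miR-450a
miR-10a-5p
miR-139-5p
miR-328a
miR-532-3p
miR-362
miR-3593-3p
miR-103
miR-539
miR-96
miR-29b
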