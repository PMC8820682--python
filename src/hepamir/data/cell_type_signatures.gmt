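HSC_up	cell_type=HSC;direction=up	let-7b	let-7c	let-7e	miR-125b-5p	miR-132	miR-143	miR-145	miR-152	miR-199a-5p	miR-21	miR-210	miR-214	miR-22	miR-221	miR-222	miR-31
HSC_down	cell_type=HSC;direction=down	miR-207	miR-335	miR-195	miR-16	miR-30a	miR-122	miR-30d	miR-30b-5p	let-7f	miR-30c	miR-194	miR-192	miR-29a	miR-26b	miR-126	miR-146a	miR-296	miR-125a-5p	miR-26a	miR-99a	miR-181a	miR-150	miR-483	miR-10a	miR-151*	miR-422b
LSEC_enriched	cell_type=LSEC;direction=enriched	miR-351	miR-335	miR-146b	miR-195	miR-322	miR-374	miR-16	miR-199a-5p	miR-10b	miR-497	miR-140	let-7i	miR-142-3p	miR-466d	miR-532-5p	miR-99b	miR-151	miR-142-5p	miR-146a	miR-125a-5p	miR-145	miR-450a	miR-10a-5p	miR-139-5p	miR-181a	miR-150	miR-328a	miR-532-3p	miR-362	miR-3593-3p	miR-126a-3p	miR-126a-5p	miR-322-3p	miR-511-3p	miR-450b-5p	miR-143-3p	miR-23a-3p	miR-338-3p	miR-130a-3p	miR-27a-3p	miR-130b-3p	miR-362-3p	miR-24-3p	miR-23b-3p	miR-29b-3p	miR-24-2-5p	miR-500-3p	miR-381-3p	miR-301a-3p	miR-3473	miR-1247-3p	miR-127-3p	miR-214-3p	miR-24-1-5p	miR-6318	miR-211-3p	miR-494-3p	miR-501-3p	miR-331-3p	miR-27b-3p	miR-149-3p	miR-150-3p	miR-92b	miR-133c	miR-139-3p	miR-290
KC_PHx3d	cell_type=KC;direction=enriched	miR-483	miR-99b	miR-103	miR-539	miR-96	miR-29b	miR-152	miR-671-3p	miR-1901	miR-465c-5p	miR-331-5p	miR-466c-5p	miR-383	miR-m108-2-5p	miR-883b-5p	miR-467e	miR-433	miR-742	miR-193b	miR-380-5p
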