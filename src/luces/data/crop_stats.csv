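# Regional crop statistics used to derive the food-production unit value E.
# yield_t_per_hm2 interprets the source yearbook's per-crop grain yield as a
# per-hectare figure (plausible agronomic range); see docs/methods.md.
crop,sown_area_hm2,yield_t_per_hm2,price_yuan_per_t
wheat,308968,5.84,2413
maize,236884,5.57,1771
sorghum,17000,3.20,2400
soybean,5206,2.64,3529
miscellaneous beans,464,1.44,3488
sweet potatoes,8127,6.59,2000
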