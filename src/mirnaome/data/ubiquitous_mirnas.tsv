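miRNA	normalised_expression
hsa-miR-486-5p	56.91769
hsa-miR-25-3p	0.263462
hsa-miR-10b-5p	14.94519
hsa-miR-99b-5p	0.033431
hsa-let-7f-5p	0.858338
hsa-miR-10a-5p	1.412167
hsa-miR-423-3p	0.060593
hsa-miR-101-3p	0.046649
hsa-miR-103a-3p	0.037811
hsa-miR-191-5p	0.548739
hsa-miR-423-5p	2.303739
hsa-miR-182-5p	0.201054
hsa-miR-30a-5p	0.134701
hsa-let-7a-5p	0.515206
hsa-miR-21-5p	0.215671
hsa-miR-150-5p	0.235879
hsa-miR-22-3p	1.557981
hsa-miR-28-3p	0.305134
hsa-let-7i-5p	0.186836
hsa-miR-30e-5p	0.036269
hsa-miR-16-5p	0.07779
hsa-miR-92a-3p	2.20284
hsa-miR-126-5p	0.271752
hsa-miR-30d-5p	0.105128
hsa-miR-451a	0.041124
hsa-miR-92b-3p	0.129143
hsa-miR-26a-5p	0.211624
hsa-miR-140-3p	0.034428
hsa-miR-375	0.295206
hsa-miR-27b-3p	0.273707
hsa-miR-143-3p	0.423736
hsa-miR-328	0.021033
hsa-miR-146b-5p	0.094907
hsa-miR-125a-5p	0.062047
hsa-miR-1246	0.050083
hsa-miR-181a-5p	1.238587
hsa-miR-222-3p	0.026529
hsa-miR-192-5p	0.196152
hsa-miR-148a-3p	0.102086
hsa-miR-146a-5p	0.399876
hsa-let-7b-5p	0.051522
hsa-miR-127-3p	0.094643
hsa-miR-151a-3p	1.164533
hsa-miR-409-3p	0.141178
hsa-miR-584-5p	0.058182
hsa-miR-186-5p	0.095506
hsa-miR-378a-3p	0.559047
hsa-miR-320a	2.876669
hsa-miR-769-5p	0.113601
hsa-miR-181b-5p	0.09218
hsa-miR-184	0.083304
hsa-miR-4448	0.04067
hsa-miR-320d	0.035856
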