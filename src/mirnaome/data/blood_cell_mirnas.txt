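hsa-miR-486-5p
hsa-miR-92a-3p
hsa-miR-181a-5p
hsa-miR-151a-3p
hsa-let-7f-5p
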