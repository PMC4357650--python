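name,hex,hexnac,dhex,neuac,neugc,reference_sodiated_mz
Man5GlcNAc2,5,2,0,0,0,1257.4225
Man3GlcNAc5,3,5,0,0,0,1542.5551
Man3Gal4GlcNAc6,7,6,0,0,0,2393.8457
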