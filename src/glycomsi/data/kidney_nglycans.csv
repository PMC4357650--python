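name,hex,hexnac,dhex,neuac,neugc,observed_awm_mz,awm_set
Man5GlcNAc2,5,2,0,0,0,1257.473,top13
Man6GlcNAc2,6,2,0,0,0,1419.532,top13
Man7GlcNAc2,7,2,0,0,0,1581.587,top13
Man8GlcNAc2,8,2,0,0,0,1743.643,top13
Man9GlcNAc2,9,2,0,0,0,1905.697,top13
Hex5HexNAc4dHex1,5,4,1,0,0,1809.69,top13
Hex4HexNAc5dHex1,4,5,1,0,0,1850.730,top13
Hex5HexNAc5dHex2,5,5,2,0,0,2158.844,top13
Hex5HexNAc5dHex3,5,5,3,0,0,2304.909,top13
Hex3HexNAc4dHex1,3,4,1,0,0,1485.591,top26
Hex4HexNAc4dHex1,4,4,1,0,0,1647.635,top26
Hex5HexNAc4,5,4,0,0,0,1663.632,top26
Hex3HexNAc5dHex1,3,5,1,0,0,1688.663,top26
Hex5HexNAc5dHex1,5,5,1,0,0,2012.773,top26
Hex10HexNAc2,10,2,0,0,0,2067.747,top26
Hex6HexNAc6dHex4,6,6,4,0,0,2816.115,top26
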