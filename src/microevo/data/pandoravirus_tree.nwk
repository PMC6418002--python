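(((p_neocaledonia:0.18,p_macleodensis:0.16)6:0.22,(p_massiliensis:0.20,p_pampulha:0.19)7:0.20)3:0.35,(p_salinus:0.16,(p_dulcis:0.13,(p_braziliensis:0.11,(p_inopinatum:0.07,(p_quercus:0.012,p_celtis:0.011)9:0.05)8:0.04)5:0.05)4:0.06)2:0.35)1;
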