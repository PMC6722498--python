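# Default CYP2D6 star-allele activity table.
# PM: nonfunctional; IM: reduced function; NM: fully functional (wild type);
# UM: increased function (duplications of NM alleles).
PM: ["*3", "*4", "*5", "*6", "*7"]
IM: ["*9", "*10", "*17", "*41"]
NM: ["*1", "*2"]
UM: ["*1XN", "*2XN"]
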