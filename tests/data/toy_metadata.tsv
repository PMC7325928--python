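sample_id	category
N1	nymph
N2	nymph
F1	female
HC1	HC
EC1	extraction_control
AC1	AC
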