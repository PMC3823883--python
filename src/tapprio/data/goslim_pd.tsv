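# Representative biological-process slim for monogenic parkinsonism
# term_id	name
GO:0008219	cell death
GO:0031396	regulation of protein ubiquitination
GO:0006950	response to stress
GO:0007005	mitochondrion organization
GO:0006914	autophagy
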