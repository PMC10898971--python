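period,total_sampled,winter_matches,Hawaii,MexMld,both
2004-2006,2022,591,533,61,3
2019-2021,2025,698,624,78,4
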