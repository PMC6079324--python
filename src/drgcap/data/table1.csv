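trust,drg370,drg371,drg372,drg373,drg373O,drg374,drg375
Helgeland,21,67,97,405,18,21,4
Nordland,119,96,382,768,19,18,0
University,268,160,502,1123,43,9,10
Finnmark,52,67,170,405,8,8,0
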