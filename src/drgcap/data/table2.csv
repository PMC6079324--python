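trust,cs_funding,vaginal_funding
Helgeland,661483,1353939
Nordland,1616123,2948855
University,3217212,4191001
Finnmark,894505,1468217
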