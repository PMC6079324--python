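trust,region
Helgeland,southern
Nordland,southern
University,northern
Finnmark,northern
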