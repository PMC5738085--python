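table,a,b,c,d
office_hours,191,6448,264,227270
both_active,191,2327,214,29252
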