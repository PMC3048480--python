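unit,period,events,ades,patient_days
PICU,pre,421,53,14027
PICU,post,410,31,14370
NICU,pre,567,75,45627
NICU,post,272,23,26122
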