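condition,codes
cardiovascular,I05-I52
cerebrovascular,G45;G46;I60-I69
kidney,N00-N19;N25-N27
liver,B18;K70-K77
respiratory,J40-J47;J60-J70;J80-J86;J96
dementia,F00-F03;F051;G30;G31
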