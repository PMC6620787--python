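# cellulose
3.2.1.21	beta-glucosidase
3.2.1.4	endoglucanase (cellulase)
3.2.1.91	cellulose 1,4-beta-cellobiosidase
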