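# starch_glucose
3.2.1.20	alpha-glucosidase
3.2.1.1	alpha-amylase
3.2.1.3	glucoamylase
3.2.1.2	beta-amylase
3.2.1.10	oligo-1,6-glucosidase
3.2.1.41	pullulanase
3.2.1.68	isoamylase
3.2.1.133	maltogenic alpha-amylase
2.4.1.19	cyclomaltodextrin glucanotransferase
2.4.1.25	4-alpha-glucanotransferase
3.2.1.54	cyclomaltodextrinase
3.2.1.70	glucan 1,6-alpha-glucosidase
5.4.99.16	maltose alpha-D-glucosyltransferase
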