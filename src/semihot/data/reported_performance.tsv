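# Published performance of the semi-supervised boosting SVM on its
# alanine-scanning benchmarks: 10-fold cross-validation on the ASEdb-derived
# training set ('asedb-cv'), on its class-balanced subset
# ('asedb-balanced-cv'), and independent tests on the BID-derived set with
# the model trained on each ('bid-independent', 'bid-independent-balanced').
# Used only for internal-consistency checks of the metric formulas.
evaluation	recall	precision	specificity	accuracy	f1
asedb-cv	0.82	0.5	0.74	0.76	0.62
asedb-balanced-cv	0.89	0.73	0.68	0.79	0.8
bid-independent	0.77	0.46	0.6	0.66	0.58
bid-independent-balanced	0.82	0.51	0.64	0.7	0.63
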