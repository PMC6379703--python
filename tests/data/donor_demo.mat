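# synthetic demonstration donor-site matrix (3 exonic + 6 intronic positions)
# consensus CAG|GTAAGT with 0.91 on the consensus base, 0.03 elsewhere
A	0.03	0.91	0.03	0.03	0.03	0.91	0.91	0.03	0.03
C	0.91	0.03	0.03	0.03	0.03	0.03	0.03	0.03	0.03
G	0.03	0.03	0.91	0.91	0.03	0.03	0.03	0.91	0.03
T	0.03	0.03	0.03	0.03	0.91	0.03	0.03	0.03	0.91
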