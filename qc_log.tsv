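# hbramp v0.1.0
# input=/tmp/pytest-of-root/pytest-5/test_selection_rejects_single_0/sim/orfeome.fasta
# n_positions=100
# seed=0
cds_id	reason
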