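# 64-unit tanh RBM for event-related (auditory-oddball-style) fMRI data
model: rbm
hidden: 64
hidden_type: tanh
epsilon: 0.08
lambda_l1: 0.1
batch_size: 5
n_epochs: 75
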