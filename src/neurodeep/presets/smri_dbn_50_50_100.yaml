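# 50-50-100 DBN for structural (gray-matter concentration) cohorts
model: dbn
arch: [50, 50, 100]
hidden_type: logistic
pretrain:
  epsilon: [0.01, 0.01, 0.001]
  lambda_l1: [0.1, 0.01, 0.001]
  dropout: [0.2, 0.5, 0.5, 0.5]
finetune:
  learning_rates: [0.01, 0.1, 1.0e-8]
  dropout: [0.7, 0.5, 0.5, 0.75]
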