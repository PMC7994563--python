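# corpus generator settings (flat key = value; see eamem.datasets.GeneratorConfig)
n_classes = 10
n_features = 64
n_per_class = 1000
class_separation = 6.0
within_spread = 1.0
seed = 1

# experiment extras picked up by eam exp1..exp5 when present
# m_values = (0, 1, 2, 3, 4, 5)
# m_bits = 5
# fold = 0
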