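# Pairwise-interaction sweep at desk scale: C, Nc and Np as functions of K.
N_list: [30]
K_list: [1, 2, 5, 8, 10, 15, 29]
k_mode: pairwise
replicates: 10
t_end: 200.0
sample_dt: 0.5
base_seed: 1
outdir: sweep_out
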