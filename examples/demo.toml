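# Demo run: fully synthetic cohort of 2,000 children under the default
# study conditions, classifier CV, 2-6-class trajectory selection, MI and
# both association analyses.  Runs in well under a minute on one core.
seed = 1

[simulate]
n_persons = 2000
seed = 1

[classifier]
k = 10
inner_k = 3
lambda_grid = [0.001, 0.01, 0.1, 1.0]

[lca]
k = 4            # used for posteriors/regressions; selection table still spans k_range
k_range = [2, 6]
n_starts = 20

[association]
by_sex = true

[mi]
m = 5
n_iter = 5
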