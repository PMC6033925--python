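# The four-iteration inference schedule of the porcine muscle study.
#
# Iteration 0 is the prior-free baseline; iterations 1-3 add the nuclear
# co-localization evidence cumulatively (prior files are incremental).
# The expression matrix is not bundled; generate a study-like synthetic one:
#
#   python -c "from colocnet.study import simulate_study_like_expression; \
#              from colocnet import io; \
#              io.write_expression_tsv(simulate_study_like_expression(seed=1)[0], \
#                                      'examples/expression.tsv')"
#   colocnet run --config examples/study_schedule.yaml --outdir results/study
#
expression: expression.tsv
iterations:
  - name: network0
    seed: 42
    target_density: 3.5
  - name: network1
    seed: 42
    target_density: 3.5
    priors: network1.priors.tsv
  - name: network2
    seed: 42
    target_density: 3.5
    priors: network2.priors.tsv
  - name: network3
    seed: 42
    target_density: 3.5
    priors: network3.priors.tsv
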