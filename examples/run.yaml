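# Full-pipeline run on a simulated cohort emulating a 10-year biannual
# OGTT study of 2,810 adults with normal glucose tolerance at enrolment.
# Replace `simulate:` with `input: path/to/cohort.csv` to analyze real data.
simulate:
  n_participants: 2810
  seed: 20260924
seed: 20260924
rule: ever-worst          # or final-visit
measures: matsuda-igi     # or external (plugged-in model-derived msi/mbcf)
outdir: glycoprog_out
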