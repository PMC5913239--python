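# Demonstration run: six-agonist synthetic panel with planted ground truth.
# The panel couples high internalization / slow recycling to reduced prolonged
# insulin secretion, so the profile stage should report a negative
# internalization-vs-ISI slope and separate the slow-internalizing,
# fast-recycling analog on PC1.
outdir: glp1pharm_demo
seed: 0
simulate: true
reference_agonist: exendin-4
reference_pathway: cAMP
trafficking_time_min: 60.0
ci_method: z
n_experiments: 5
dose_response_cv: 0.10
kinetics_cv: 0.01
trafficking_cv: 0.03
ph_cv: 0.01
secretion_cv: 0.08
tracer_k1: 2.0e+8
tracer_k2: 0.08
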