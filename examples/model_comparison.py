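"""Evidence-based model comparison: laminar circuit vs Jansen-Rit.

Generates data from the laminar circuit with its cross-laminar features
active (parallel layer-4 -> layer-5/6 pathway, cross-layer inhibition),
fits both candidate models, and prints the log Bayes factor.  A difference
of log evidences of three or more counts as strong evidence.  Takes a few
minutes on one CPU.
"""

from lccm import model_recovery_experiment

table = model_recovery_experiment(n_seeds=2, noise_sd=0.05, seed0=0)
print(table.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print("\nln B = F_lccm - F_jrm >= 3 means the data strongly favor the laminar")
print("model that generated them; the three-population baseline cannot")
print("reproduce the cross-laminar waveform features at the noise level.")
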