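"""End-to-end generative run with the equivalence battery.

Simulates a 191-subject cohort, reduces it to the eigen-wavefront basis,
fits the two-component Gaussian mixture by EM, samples 1000 synthetic
accommodative wavefront sets and validates them against the source
cohort (KS normality, TOST equivalence of means, F-test of variances,
Bonferroni-corrected per family).
"""

from accowave import PipelineConfig, run_pipeline

artifacts = run_pipeline(PipelineConfig(seed=7, output_dir="scratch_run"))

log = artifacts["log"]
print(f"K retained: {log['k_retained']} "
      f"({100 * log['variance_retained']:.4f}% variance)")
print(f"EM mixture weights: {[round(w, 3) for w in log['em_weights']]}")
print(artifacts["report_eigenvectors"].summary())
print(artifacts["report_zernike"].summary())
# TOST passes everywhere (synthetic means track the source means); F-test
# failures concentrate in high-order modes whose variance the 99.97% cutoff
# discards — the known compression cost of the eigen-wavefront truncation.
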