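"""Full simulated study: cohort -> FAIR + PCMRI -> LPS shift -> statistics.

Runs every pipeline stage at a reduced matrix (32) with a small cohort so
the example finishes in seconds, then prints the rendered report: baseline
sham/BDL comparisons, FAIR-vs-PCMRI agreement, and the group x time mixed
ANOVA of the LPS response.  Intermediate NIfTI/CSV files are persisted
under the output directory; re-running only the stats stage reproduces the
report exactly.
"""

from hepaflow import CohortConfig, RunConfig, report_render, run_study

config = RunConfig(
    cohort=CohortConfig(n_sham=5, n_bdl=5, seed=2),
    matrix=32, noise_sd=10.0, phase_noise_sd=0.02,
    seed=2, outdir="study_out_example")

report = run_study(config)
print(report_render(report.report))
print(f"\nintermediates persisted under: {report.outdir}")
# Interaction power at the default (literature-derived) effect sizes is moderate (~60%), so a
# single small replicate may or may not reach p < 0.05; the cohort means,
# the T1 gap (~1256 vs ~1533 ms) and the perfusion deficit in BDL animals
# mirror the generator's configured distributions.
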