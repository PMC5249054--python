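# Known discordances when the sample-level morphology rules are re-applied to the
# bundled reference-cohort aggregates (rule inputs reconstructed from the printed
# per-sample means, so diameters carry the table's quantization). All other
# non-excluded samples are expected to reproduce their recorded flags exactly.
sample_id,recorded_flags,computed_flags,note
3,fp,"fl,fp","mean SMI 2.95 and d_cube ~187 um satisfy the literal fl rule as well; the recorded table shows fp only, suggesting a precedence rule or per-object evaluation in the original analysis. Recorded as a known discordance, not absorbed."
15,ch,ns,"ch requires the largest object's sphere-equivalent diameter > 500 um; only the sample mean volume is available in the summary table, whose equivalent diameter (~449 um) falls below the threshold. Reproducing ch for this sample needs per-object sizes, which the summary table does not carry."
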