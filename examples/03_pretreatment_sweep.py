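"""Compare pretreatments by their false-positive rate and AUC.

On the dominant-peak fixture, sweeps all pretreatments and reports, per
method, the linkage thresholds at the 95%/99% confidence limits, the
FN%/FP% they produce, and the ROC AUC. The FP rate at the 95% limit is the
figure of merit in forensic linkage - an unlinked pair called linked is
the costly error.
"""

from chromalink import SynthConfig, evaluate_pretreatments, generate_dataset

dataset = generate_dataset(
    SynthConfig(
        n_groups=8, samples_per_group=6, n_points=1200, n_peaks=25,
        shift_sd=0.0, inter_sd=0.4, intra_sd=0.12, seed=11,
    )
)
table = evaluate_pretreatments(dataset)
print(table.round(3).to_string())
print()
fp_none = table.loc["none", "fp_95"]
fp_root = table.loc["fourth_root", "fp_95"]
print(f"fourth-root transform cuts FP at the 95% limit from {fp_none:.1f}% to {fp_root:.1f}%")
print("by compressing the dominant peak that makes every pair look alike;")
print("row-standardising methods (norm_cc, snv_cc) leave the masking in place.")
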