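"""Correct retention-time drift by Correlation-Optimized Warping.

Simulates fingerprints with run-to-run retention shifts, picks warping
parameters with the automated search (ACOW), aligns every trace to the
automatically selected reference, and shows the gain in within-site
correlation.
"""

from chromalink import (
    SynthConfig,
    acow_optimize,
    correlation_structure,
    cow_set,
    generate_dataset,
)

dataset = generate_dataset(
    SynthConfig(
        n_groups=3, samples_per_group=4, n_points=800, n_peaks=15,
        shift_sd=4.0, seed=2,
    )
)
before = correlation_structure(dataset).intra_r.mean()

params = acow_optimize(dataset, sl_range=(20, 60), ss_range=(2, 6))
result = cow_set(dataset, params)
after = correlation_structure(result.aligned).intra_r.mean()

print(f"chosen parameters: segment length SL={params.sl}, slack SS={params.ss}")
print(f"reference sample index: {result.reference_index}")
print(f"mean intra-site r before alignment: {before:.4f}")
print(f"mean intra-site r after alignment:  {after:.4f}")
print()
print("Warping removes the retention drift, so plants from the same site")
print("correlate more strongly; differences that remain are compositional.")
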