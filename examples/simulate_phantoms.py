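"""Generate the 28-stack touching-pair phantom series and write it to disk.

Each stack holds one pair of radius-10-um spherical somas on a Poisson
background (mean 100), at one of 4 SNR levels and 7 centre distances.
"""

from pathlib import Path

from somapeaks import io, phantom

out = Path("scratch/phantoms")
out.mkdir(parents=True, exist_ok=True)

series = phantom.generate_pair_series(seed=0)
for snr, d, stack, truth in series:
    tag = f"snr{snr:g}_d{d:g}"
    io.write_stack(out / f"stack_{tag}.tif", stack)
    io.write_truth_csv(out / f"truth_{tag}.csv", truth)

print(f"wrote {len(series)} stacks to {out}/")
print("each stack: 100^3 voxels of 2x2x2 um^3, one soma pair, Poisson noise")
i_o = phantom.snr_to_intensity(1.0, 100.0)
print(f"at SNR=1 the soma signal mean is I_o = {i_o:.2f} counts over background 100,")
print("i.e. barely one noise standard deviation - the hardest condition in the series.")
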