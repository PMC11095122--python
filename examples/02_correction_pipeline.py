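"""Correct a distorted sinogram by rearrangement and quantify the gain.

Simulates a mismatched acquisition (medium 1.4, specimen 1.3), corrects it
with the entry-point table built from the known surface, reconstructs all
three variants by filtered back projection and scores them with SSIM/APD
against the matched reference.
"""

from slotsim import (
    OpticalConfig,
    apd,
    build_entry_table,
    fbp,
    make_phantom,
    make_rois,
    rearrange_sinogram,
    simulate_sinogram,
    ssim,
)
from slotsim.recon import recon_to_uint8

pair = make_phantom(seed=1, size=(256, 256), pattern="logo_like")
P = 400

reference = recon_to_uint8(fbp(simulate_sinogram(
    pair, OpticalConfig(1.4, 1.4, P)))).astype(float)

cfg = OpticalConfig(1.4, 1.3, P)
sino = simulate_sinogram(pair, cfg)
table = build_entry_table(pair.surface, cfg, center=pair.rotation_center)
print(f"entry table: {table.shape[0]} projections x {table.shape[1]} columns, "
      f"unrecoverable fraction {table.invalid_fraction():.3f}")

corrected = rearrange_sinogram(sino, table)
rec_uncorrected = recon_to_uint8(fbp(sino)).astype(float)
rec_corrected = recon_to_uint8(fbp(corrected)).astype(float)

whole, central = make_rois(pair.surface, center=pair.rotation_center)
for name, rec in (("uncorrected", rec_uncorrected),
                  ("corrected", rec_corrected)):
    print(f"{name:12s} SSIM(whole)={ssim(rec, reference, whole):.3f} "
          f"SSIM(central)={ssim(rec, reference, central):.3f} "
          f"APD(whole)={apd(rec, reference, whole):.1f}")
print("SSIM runs from 0 (unrelated) to 1 (identical); APD is the mean "
      "absolute 8-bit brightness difference (0 = perfect). At this 0.1 "
      "index mismatch rearrangement recovers most of the structural "
      "similarity the distortion destroyed.")
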