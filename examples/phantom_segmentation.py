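"""Contrast-free active-lesion segmentation on a synthetic brain slice.

Generates the default multiparametric phantom (PD / T2W / FLAIR / T1pre
plus a held-out post-contrast T1post), embeds the four non-contrast
channels into a single image with Isomap and LLE, thresholds both the
embedding and the T1post - T1pre subtraction image, and prints the Dice
overlap between the two masks.  A Dice near 1 means the embedding found
the enhancing (active) lesions without ever seeing the contrast scan.
"""
import manifoldseg as ms

phantom = ms.make_phantom(ms.PhantomSpec(seed=0))
print(f"phantom: {phantom.volume.shape} grid, "
      f"{int(phantom.lesion_mask.sum())} lesion px, "
      f"{int(phantom.active_mask.sum())} active px")

for method in ("isomap", "lle"):
    cfg = ms.RunConfig(method=method, seed=0)
    res = ms.segment_volume(phantom, cfg)
    p = res.provenance
    print(f"\n{method}: Dice = {res.dice_result.dice:.3f} "
          f"(TP={res.dice_result.tp}, FP={res.dice_result.fp}, "
          f"FN={res.dice_result.fn})")
    print(f"  codebook {p['n_codewords']} signatures, K_eff={p['k_effective']}, "
          f"backend={p['geodesic_backend']}, threshold={p['embedded_threshold']:.3f}")
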