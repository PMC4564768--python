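"""Rasterise a corolla into a noisy scan-like voxel stack and segment it back.

The voxel export adds the two artefacts a mounted specimen scan shows: a
bright half-disc fastening base at the bottom of every slice and isolated
bright "sparkle" voxels in the background.  The per-slice segmentation
chain (base removal, contrast stretch, Otsu binarisation, small-object
removal, masking + radius-1 closing) removes both, and marching cubes
turns the cleaned volume into a surface mesh in mm.
"""

from floramorph import (FlowerParams, SegmentationConfig, extract_surface,
                        make_flower, segment_stack, voxelize)

params = FlowerParams(voxel_size_um=150.0, noise_sparkle_density=2e-4,
                      base_height=3.0, seed=4)
mesh, gt = make_flower(params)
volume = voxelize(mesh, params)
print(f"raw volume: {volume.shape} voxels at {volume.voxel_size_um:.0f} um, "
      f"{volume.foreground_count()} foreground")

segmented = segment_stack(volume, SegmentationConfig())
print(f"segmented : {segmented.foreground_count()} foreground "
      f"(base and sparkles removed)")

surface = extract_surface(segmented)
print(f"extracted surface: {len(surface.vertices)} vertices, "
      f"{len(surface.faces)} faces")
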