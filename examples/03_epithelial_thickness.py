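"""Epithelial thickness (VET) from a structural B-scan.

The epithelium is the dark band between the bright surface reflection and
the bright lamina propria.  The classical segmenter tracks both
boundaries by dynamic programming; thickness is their separation scaled
by the axial pixel size (14 um here).
"""

from endooct import (
    PhantomGeometry,
    compute_vet,
    make_tissue_scene,
    render_frame_sequence,
    segment_epithelium_classical,
)

geometry = PhantomGeometry()
for thickness in (100.0, 150.0, 200.0):
    scene = make_tissue_scene(geometry, thickness_um=thickness,
                              vessel_fraction=0.0, seed=5)
    volume = render_frame_sequence(scene, decorrelation=0.0,
                                   noise_floor=0.05, seed=6)
    bscan = volume.structural_bscan(geometry.n_slow // 2)
    segmentation = segment_epithelium_classical(bscan)
    profile = compute_vet(segmentation, geometry.axial_pixel_um)
    print(f"true thickness {thickness:5.0f} um -> measured mean VET "
          f"{profile.mean_vet_um:5.1f} um "
          f"(valid columns: {profile.valid_fraction:.0%})")
# Recovery is accurate to about one axial pixel (14 um) — the resolution
# floor of any boundary measurement on this grid.
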