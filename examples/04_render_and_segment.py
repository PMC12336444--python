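"""Render a slide to a 4-channel image and segment it back.

Shows the imaging leg of the pipeline: cells are rasterized as flux-
normalized disks convolved with a Gaussian PSF (DAPI, CKmix, CD45, MSLN
channels), then nuclei are re-segmented by Otsu thresholding of the DAPI
channel and per-cell channel totals are re-extracted.  Without noise the
recovered totals match the specified ones to within 1% (flux conservation).
"""

import pandas as pd

from ctcdx import SlideSimConfig, render_images
from ctcdx.slides import classify_cells, count_ctcs, segment_cells

cfg = SlideSimConfig(image_shape=(256, 256), pixel_size=0.5, psf_sigma=1.5,
                     background=50.0)

cells = pd.DataFrame([
    # one MSLN-positive CTC, one plain CTC, two leukocytes
    dict(slide_id="s", cell_id="tumor_msln", x_um=40.0, y_um=40.0, area_um2=80.0,
         int_dapi=15000.0, int_ckmix=7000.0, int_cd45=250.0, int_msln=8000.0),
    dict(slide_id="s", cell_id="tumor_plain", x_um=90.0, y_um=60.0, area_um2=78.0,
         int_dapi=15000.0, int_ckmix=6800.0, int_cd45=260.0, int_msln=80.0),
    dict(slide_id="s", cell_id="wbc_1", x_um=60.0, y_um=100.0, area_um2=30.0,
         int_dapi=10000.0, int_ckmix=250.0, int_cd45=6000.0, int_msln=380.0),
    dict(slide_id="s", cell_id="wbc_2", x_um=100.0, y_um=100.0, area_um2=31.0,
         int_dapi=10500.0, int_ckmix=240.0, int_cd45=6100.0, int_msln=370.0),
])

stack = render_images(cells, cfg)
print("rendered image stack:", stack.shape, "(channels DAPI, CKmix, CD45, MSLN)")

segmented = segment_cells(stack, pixel_size=cfg.pixel_size, min_area=10.0)
print(f"\nsegmented {len(segmented)} nuclei; recovered features:")
print(segmented[["x_um", "y_um", "area_um2", "int_ckmix", "int_cd45",
                 "int_msln"]].round(1).to_string(index=False))

called = classify_cells(segmented)
msln_n, ctc_n = count_ctcs(called)
print("\ncalled classes:", called["called_class"].tolist())
print(f"counts -> MSLN(+)CTC: {msln_n}, CTC (incl. MSLN-positive): {ctc_n}")
# expected: 1 MSLN(+)CTC and 2 CTCs total; the small nucleus of a leukocyte
# (<47 um^2) can never be promoted to an MSLN-positive call.
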