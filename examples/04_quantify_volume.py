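"""Convert masks to physical areas, distribution indices, and volumes.

Uses the acquisition geometry (FOV / grid) to express a phantom's
compartments in cm^2, then aggregates a stack of slice areas into a
volume.
"""

from slicefat.phantom import PhantomSpec, generate_slice_phantom
from slicefat.quantify import (
    PixelGeometry,
    VolumeSpec,
    distribution_indices,
    surface,
    volume,
)

spec = PhantomSpec(noise_sd=0.0, seed=1)
_, truth, _, _ = generate_slice_phantom(spec)

# 1 mm x 1 mm pixels: FOV in mm equals the grid size
geom = PixelGeometry(
    fov_row_mm=float(spec.image_height_px),
    fov_col_mm=float(spec.image_width_px),
    n_rows=spec.image_height_px,
    n_cols=spec.image_width_px,
)
sat = surface(truth.sat, geom)
vat = surface(truth.vat, geom)
report = distribution_indices(sat, vat)
print(f"SAT {report.sat_cm2:.2f} cm^2, VAT {report.vat_cm2:.2f} cm^2, "
      f"TAT {report.tat_cm2:.2f} cm^2")
print(f"VAT/TAT {report.vat_tat_pct:.1f} %, VAT/SAT {report.vat_sat_ratio:.3f}")

# volume from a stack of slices: 5 mm thickness, 1.5 mm gap
stack = VolumeSpec(
    slice_thickness_t_cm=0.5,
    between_slice_gap_h_cm=0.15,
    areas_cm2=(vat, vat * 1.1, vat * 0.9),
)
print(f"VAT volume over 3 slices: {volume(stack):.2f} cm^3")
# Areas are pixel counts x pixel area; the volume treats each slice area
# as a slab of extent (thickness + gap) along the scan axis.
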