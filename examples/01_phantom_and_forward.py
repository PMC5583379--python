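"""Build a treated-tumor phantom and solve the forward electric problem.

A 64x64 / 30 mm conductivity map holds a 2.2 mm-radius tumor (0.4 S/m) in
background tissue (0.2 S/m); two 0.5 mm needle electrodes 2.2 mm apart are
driven at 700 V.  The script solves the potential, derives the field and
current maps, and summarizes the field inside the tumor.
"""

from iremap import (
    GridSpec,
    PulseProtocol,
    compute_fields,
    field_summary,
    make_phantom,
    solve_potential,
)

grid = GridSpec(n_x=64, n_y=64, fov_mm=30.0)
phantom = make_phantom(
    grid,
    tumor_radius_mm=2.2,
    sigma_background=0.2,
    sigma_tumor=0.4,
    electrode_gap_mm=2.2,
    voltage=700.0,
    seed=0,
)

u = solve_potential(phantom.sigma_true, phantom.electrodes)
e_map, j_map = compute_fields(u, phantom.sigma_true)

summary = field_summary(e_map, phantom.tumor_mask, thresholds_kv_cm=(1.8,))
print(f"potential range: {u.data.min():.0f} .. {u.data.max():.0f} V")
print(f"peak field in tumor: {summary['max_kv_cm']:.2f} kV/cm")
print(f"mean field in tumor: {summary['mean_kv_cm']:.2f} kV/cm")
frac = summary["fraction_above"][1.8]
print(f"tumor fraction above 1.8 kV/cm (necrosis-associated field): {frac:.1%}")
# The peak sits at the electrodes and decays outward; the fraction above
# 1.8 kV/cm is the part of the tumor cross-section expected to necrose.
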