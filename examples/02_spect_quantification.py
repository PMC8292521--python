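"""Quantify kidney activity from a simulated SPECT study.

Runs the full chain twice: once with the true attenuation map and once with
the map derived from the scatter-window data (the CT-less clinical route),
then reports the recovered fraction of injected activity.
"""

import numpy as np

import dmsapk as d
from dmsapk.spect import MuMap

phantom = d.make_phantom()
geometry = d.AcquisitionGeometry(n_views=60, orbit_radius_cm=15.0)
sens = d.SensitivityFactor(5000.0)
resp = d.CollimatorResponse()
t_img = 3.0

projections = d.simulate_acquisition(phantom, geometry, sens, t_img, noise=True,
                                     seed=7, response=resp,
                                     photopeak_scatter_fraction=0.2)
truth = phantom.kidney_activity_mbq * d.decay_factor(t_img)
print(f"decayed kidney truth at {t_img} h: {truth:.2f} MBq")

zs = np.where(phantom.kidney_mask.any(axis=(0, 1)))[0]
maps = {
    "true attenuation map": MuMap(phantom.mu_grid, provenance="true"),
    "scatter-window-derived map": d.attenuation_map_from_scatter_window(
        projections, (int(zs.min()), int(zs.max()) + 1)
    ),
}
for label, mu_map in maps.items():
    image = d.reconstruct_osem(projections, mu_map, resp, sens,
                               n_iterations=5, n_subsets=16)
    activity, voi = d.kidney_activity_from_image(image)
    frac = d.fraction_injected(activity, phantom.injected_activity_a0_mbq, t_img)
    print(f"{label}: {activity:.2f} MBq ({100 * (activity - truth) / truth:+.1f}% "
          f"error), fraction of injected activity {frac:.3f}")
# With accurate attenuation the error is a few percent; the scatter-window
# route adds the body-contour uncertainty and stays within ~10-15%.
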