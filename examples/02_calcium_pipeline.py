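"""Quantify dendritic calcium transients in a simulated GCaMP movie.

Builds two noiseless movies that differ only in how far each transient
spreads along the dendrite — compartmentalized (sigma = 2 px, spine-like)
vs diffuse (sigma = 20 px, shaft-spreading) — runs the kymograph pipeline
on both and prints the per-site read-outs.
"""

import synaptodev as sd

for label, sigma in [("compartmentalized", 2.0), ("diffuse", 20.0)]:
    params = sd.CalciumSimParams(
        n_frames=600, n_sites=3, roi_length=400,
        transient_rate=5.0,      # events per 500 frames per site
        amplitude=2.0,           # peak dF/F0
        spatial_sigma=sigma,     # px; 65 px = 10 um
        noise_sd=0.5, seed=8,
    )
    movie, roi, truth = sd.gen_calcium_movie(params)
    result = sd.analyze_movie(movie, roi, sync_seed=0)
    print(f"\n{label} transients (spatial sigma = {sigma:g} px):")
    for m in result["metrics"]:
        print(
            f"  site {m.site_id}: AUC = {m.auc:6.2f} dF/F0*px, "
            f"diffusion distance = {m.diffusion_distance_um:5.2f} um, "
            f"frequency = {m.frequency_per_500:.2f}/500 frames"
        )
# Diffuse signals cover a longer stretch of dendrite at the same event rate,
# so their diffusion distance (span above 10% of peak) and AUC are larger —
# the signature used to separate shaft-spreading from spine-restricted
# calcium activity.
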