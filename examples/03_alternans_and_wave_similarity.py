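"""Beat-to-beat alternans (dAPD80) and optical wave similarity (OWS).

A movie with programmed 10 ms APD alternation demonstrates the
single-beat analyses: dAPD80 (mean absolute APD difference between
consecutive beats) recovers the programmed magnitude, and OWS — the mean
pairwise cosine similarity of amplitude-normalised single beats — drops
below 1 because odd and even beats differ in shape.
"""

import numpy as np

from cardiomap import (
    SimulationSpec,
    alternans_map,
    apply_polarity,
    detect_beats,
    gaussian_spatial_filter,
    global_signal,
    identify_pcls,
    ows_map,
    segment_tissue,
    simulate_paced_movie,
)

for delta in (0.0, 10.0):
    spec = SimulationSpec(apd80=60.0, alternans_delta=delta,
                          pcl_schedule=((160.0, 10),), seed=3)
    movie, truth = simulate_paced_movie(spec)
    movie = apply_polarity(movie)
    mask = segment_tissue(movie)
    movie = gaussian_spatial_filter(movie, mask=mask)
    table = identify_pcls(detect_beats(global_signal(movie, mask), 1000.0),
                          1000.0)
    dmap = alternans_map(movie, table, 0, mask, pre_ms=30, post_ms=120)
    omap = ows_map(movie, table, 0, mask)
    print(f"programmed alternation {delta:4.1f} ms -> "
          f"dAPD80 map mean {np.nanmean(dmap.values):5.2f} ms, "
          f"OWS map mean {np.nanmean(omap.values):.4f}")
# With no alternation dAPD80 sits at the noise floor and OWS at 1.0;
# with 10 ms alternation dAPD80 reports ~10 ms and OWS dips slightly.
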