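"""Scaled-down arm-cuff occlusion through the full pipeline.

Simulates a piecewise-stationary 8-channel packed stream (baseline ->
occlusion with a 100x flow drop -> recovery), runs unpack -> correlate ->
channel-average -> fit, and prints the per-segment median flow index with a
smoothed time course.
"""

import numpy as np

from cdcs import (
    AcquisitionSpec,
    OpticalProperties,
    RunConfig,
    moving_average,
    run_pipeline,
    simulate_occlusion_series,
)

acq = AcquisitionSpec(1e6, 0.1, n_channels=8)  # 10 Hz flow estimates
optics = OpticalProperties.from_nm(0.1, 10.0, 785.0)

stream, truth = simulate_occlusion_series(
    baseline_F=1e-8, occluded_F=1e-10, segment_durations_s=[2.0, 2.0, 2.0],
    acquisition=acq, seed=11,
)
cfg = RunConfig(acq, optics, rho_groups={1.0: [0, 1, 2], 2.5: [3, 4, 5, 6, 7]})
result = run_pipeline(stream, cfg)

for rho, df in result.flow_tables.items():
    print(f"\nrho = {rho} cm ({len(df)} frames at 10 Hz):")
    for _, seg in truth.iterrows():
        sel = df[(df.time_s > seg.t_start_s) & (df.time_s <= seg.t_end_s)]
        med = sel.F_cm2_s.median()
        print(f"  {seg.segment:10s} true F = {seg.F_cm2_s:.1e}  "
              f"median fitted F = {med:.2e} cm^2/s")
    drop = 1 - df[df.time_s <= 4].F_cm2_s[20:].median() / df.F_cm2_s[:20].median()
    smooth = moving_average(df.F_cm2_s.to_numpy(), 5)
    print(f"  measured occlusion drop: {100*drop:.1f}%  "
          f"(smoothed trace min {smooth.min():.2e}, max {smooth.max():.2e})")
# Both separations track the ~99% flow reduction and the recovery, showing
# the dynamic range of the compressed counting chain end to end.
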