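"""Error introduced by assuming a fixed viewing distance.

A participant actually standing at 800 mm is processed twice: once
assuming the default 600 mm fixed perpendicular viewing position and
once with the viewing position estimated from the marker array.  The
accuracy ratio shows the inflation caused by the wrong distance
assumption (~133% here, approximately 800/600 for near-centre gaze).
"""

import gazeval as gv

poster = gv.default_poster()
cfg = gv.SimulationConfig(
    poster=poster,
    offset_deg=(0.5, 0.0),
    eye_trajectory=gv.trajectory_static((0.0, 0.0, -800.0)),
)
rec, _ = gv.simulate_recording(cfg)
fixed = gv.process_episode(rec, rec.episodes[0], poster,
                           mode="fixed_distance", assumed_distance=600.0)
pose = gv.process_episode(rec, rec.episodes[0], poster, mode="pose_estimated")

centre_f = next(r for r in fixed.results if r.target_id == 5)
centre_p = next(r for r in pose.results if r.target_id == 5)
ratio = gv.fixed_distance_error_ratio(centre_f, centre_p)
print(f"central target accuracy, fixed-600mm mode:  {centre_f.accuracy_deg:.3f} deg")
print(f"central target accuracy, pose-estimated:    {centre_p.accuracy_deg:.3f} deg")
print(f"estimated viewing distance: {centre_p.viewing_distance_mm:.0f} mm (true 800)")
print(f"accuracy error ratio: {ratio['accuracy_pct']:.1f}% "
      "(fixed/physical x 100; 100% means no error)")
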