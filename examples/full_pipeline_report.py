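"""The contextualized gait report: video context fused with IMU gait.

Generates a synchronized synthetic episode (100 scene frames across a
60 s walk plus an accelerometer trace), runs both analysis streams, and
prints the fused per-bout report.
"""

import json

from gaitcontext import (
    GaitSimConfig,
    SceneConfig,
    align,
    build_report,
    build_walking_path,
    compute_temporal_stats,
    detect_bouts,
    detect_gait_events,
    generate_gait_signal,
    generate_scene_sequence,
    load_taxonomy,
    summarize_bout_context,
)
from gaitcontext.fusion import report_to_dict
from gaitcontext.path_overlap import analyze_frame

tax = load_taxonomy("builtin")
rest, duration, n_frames = 5.0, 60.0, 100
scene_cfg = SceneConfig(n_frames=n_frames, fps=n_frames / duration, time_offset=rest,
                        hazard_in_path_prob=0.35, seed=31)
frames, _, scene_truth = generate_scene_sequence(scene_cfg, tax)
signal, _ = generate_gait_signal(GaitSimConfig(duration=duration, rest_padding=rest, seed=32))

path = build_walking_path(scene_cfg.width, scene_cfg.height, scene_cfg.path)
contexts = [analyze_frame(f, path, tax) for f in frames]
(bout,) = detect_bouts(signal)
stats = compute_temporal_stats(detect_gait_events(signal, bout))
mapping = align(contexts, [bout], tolerance=0.5)
summary = summarize_bout_context(bout, mapping[0], tax)
report = build_report([(bout, stats)], [summary])

print(json.dumps(report_to_dict(report), indent=2, sort_keys=True))

# hazard_in_path_fraction: share of the bout's video frames with a
# fall-risk object inside the walking path; unattended_hazard_windows:
# 2-second spans where a hazard was present but never gazed at. The gait
# block gives step/stance/swing mean, variability and asymmetry for the
# same bout, so instability can be read against its environmental context.
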