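"""Synchronize a hand-built trial and compute occupancy-normalized scores.

A 60 s toy trial: the animal spends the first 40 s in the social-reward
arm emitting trills, then 20 s in the sucrose arm emitting flats.  The
combined vocalization score (CVS, call frames per occupied second) and
the per-subtype scores (SVS) normalize away how long each zone was
visited.
"""

from usvscore.io_formats import CallLabel, TrackRecord, default_zone_map
from usvscore.scoring import cvs_frames, svs_table
from usvscore.sync import assign_zones, rasterize_labels, select_channel, tabulate

zone_map = default_zone_map()

calls = [
    CallLabel(5.0, 5.04, "Trill", amplitudes=(-38.0, -45.0, -52.0, -50.0)),
    CallLabel(12.0, 12.05, "Trill", amplitudes=(-36.0, -44.0, -51.0, -49.0)),
    CallLabel(30.0, 31.5, "22kHz", amplitudes=(-40.0, -42.0, -44.0, -46.0)),
    CallLabel(45.0, 45.03, "Flat", amplitudes=(-50.0, -39.0, -48.0, -52.0)),
]
print("loudest channel per call:",
      [select_channel(c) for c in calls])

# 25 Hz tracking: 40 s in the north (social) reward zone, 20 s east
tracks = [TrackRecord(k / 25.0, 0.0, 70.0) for k in range(1000)] + \
         [TrackRecord(k / 25.0, 70.0, 0.0) for k in range(1000, 1500)]

frames = rasterize_labels(calls, frame_rate=25.0, duration=60.0)
timeline = assign_zones(tracks, zone_map, frame_rate=25.0, duration=60.0)
counts = tabulate(frames, timeline)

print(f"\nN_reward occupancy: {counts.occupancy_seconds('N_reward'):.0f} s, "
      f"50-kHz call frames: {cvs_frames(counts, 'N_reward')}")
svs = svs_table(counts, zones=("N_reward", "E_reward"))
print("\nper-zone scores (frames/s):")
print(svs[["occupancy_s", "Trill", "Flat", "CVS"]].round(4).to_string())

# Note the 1.5 s alarm call: it fills ~38 raster frames but is excluded
# from CVS, which counts only the fifteen 50-kHz labels.
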