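"""Adhesion dynamics in a colony movie: edge-stable vs centre-dynamic.

Generates a labeled adhesion movie (stable cornerstone adhesions in a
5-um edge strip, short-lived adhesions in the centre), tracks regions by
pixel overlap, and compares per-class lifetimes and colony coverage.
"""
import numpy as np

from fastrata import ColonySpec, MovieSpec, generate_adhesion_movie, summarize_dynamics

colony = ColonySpec(image_shape=(192, 192), pixel_um=0.5, edge_strip_um=5.0,
                    n_edge_fa=10, n_centre_fa=25)
movie = MovieSpec(n_frames=105, frame_interval_min=1.0, seed=2)
stack, truth = generate_adhesion_movie(colony, movie)

tracks, summary = summarize_dynamics(
    stack, truth.edge_mask, truth.centre_mask, pixel_um=0.5,
    frame_interval_min=1.0, cap_min=105.0,
)

edge_lt = tracks.by_class("edge").lifetimes_min(cap_min=105)
centre_lt = tracks.by_class("centre").lifetimes_min(cap_min=105)
print(f"tracks: {len(tracks.tracks)} "
      f"({len(edge_lt)} edge, {len(centre_lt)} centre)")
print(f"median lifetime: edge {np.median(edge_lt):.0f} min, "
      f"centre {np.median(centre_lt):.0f} min (cap 105 min)")
print(f"mean coverage: edge {summary.coverage_pct['edge'].mean():.1f} %, "
      f"centre {summary.coverage_pct['centre'].mean():.1f} %")

# Edge adhesions persist for the whole movie (lifetimes pinned at the
# cap) while centre adhesions turn over in tens of minutes — the
# stability contrast that defines cornerstone adhesions.
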