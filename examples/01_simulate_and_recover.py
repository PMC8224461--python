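"""Simulate a transient surface wave and recover its group velocity.

A wave with known ground-truth speed propagates bilaterally from the line
center; the OCE chain (phase encoding -> displacement -> depth-averaged
spatiotemporal map -> cross-correlation time-of-flight) estimates it back.
"""
import elastowave as ew

TRUE_SPEED = 2.8  # m/s

geom = ew.oce_geometry()  # 251 points over 7.83 mm, 30 kHz, 1310 nm
pulse = ew.default_pulse("OCE")  # 573 Hz Gaussian-enveloped cosine, 0.5 um peak

field = ew.make_displacement_field(geom, TRUE_SPEED, pulse, seed=1)
frames = ew.encode_oce_frames(field, noise_sd_phase=0.1, seed=1)
displacement = ew.oce_phase_to_displacement(frames)
st_map = ew.depth_average(displacement)  # 400 um below the surface
est = ew.estimate_group_velocity(st_map)

print(f"ground truth speed : {TRUE_SPEED:.3f} m/s")
print(f"estimated speed    : {est.speed:.3f} m/s")
print(f"side speeds (L, R) : {est.side_speeds[0]:.3f}, {est.side_speeds[1]:.3f} m/s")
print(f"fit r^2            : {est.r_squared:.5f}")
# The estimate is the mean of independent fits on the two propagation
# sides; with 0.1 rad phase noise it lands within ~1% of ground truth.
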