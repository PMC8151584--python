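# Default operating point of the trapmatch pipeline.  Every pipeline
# constant lives here; the code reads them from the loaded config.

[image]
width = 1280
height = 960

[template]
width = 200
height = 144

[detection]
threshold = 0.4          # chosen among {0.4, 0.45, 0.5}: best rate/accuracy trade-off
enable_padding = true
enable_covering = true
max_detections = 100
pad_fill = "median"

[classification]
# Midpoints between the per-class mean features of 200 seeded synthetic
# insects at default generator parameters (scripts/calibrate_thresholds.py).
theta1 = 0.2165          # perimeter/area threshold
theta2 = 38.0            # perimeter^2/area threshold
morph_size = 3

[evaluation]
match_tol = 100.0        # pixels; half the template width

[scene]
background_intensity = 30.0
illumination_gradient = 40.0
noise_sigma = 5.0
contrast = 140.0
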