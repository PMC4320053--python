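# Default model configuration.
#
# Sensory noise: visual spatial SD 1 mm, proprioceptive SD 15 mm, visual and
# tactile temporal SDs 20 ms; prior probability of a common cause 0.5.
# The prior widths sigma_x / sigma_t approximate uniform priors but their
# exact value matters through the Occam factor, so they are calibrated, not
# guessed: the values below are the output of `rhi calibrate --target "30 cm"`
# (the separation at which the illusion is known to fade), i.e. the widths at
# which a noise-free synchronous trial at a 30 cm hand separation sits at
# posterior 0.5 exactly.  See the calibration section for provenance.
model:
  sigma_v: 1 mm
  sigma_p: 15 mm
  sigma_tv: 20 ms
  sigma_tt: 20 ms
  include_temporal: true
  priors:
    mu_x: 0 mm
    sigma_x: 3.561083006435969e+44 mm
    mu_t: 0 ms
    sigma_t: 3.561083006435969e+44 ms
    p_common: 0.5
simulation:
  default_trials: 100000
  illusion_threshold: 0.5
  async_offset: 750 ms      # midpoint of the 0.5-1 s asynchronous stroking lag
  true_x_v: 16 cm           # rubber hand azimuth (midline = 0)
  true_x_p: 32 cm           # real hand azimuth
calibration:
  target_vanish_distance: 30 cm
  method: root of the noise-free synchronous posterior log-odds on log sigma_x
    (sigma_t moved by the same log-factor)
  generated_by: rhi calibrate
  timestamp: "2026-09-20T00:00:00+00:00"
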