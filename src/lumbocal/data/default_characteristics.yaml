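# Default characteristic parameter set of the lumbar motion-segment model:
# the calibrated L4-L5 disk, facet and ligament parameters extracted from
# stepwise-reduction range-of-motion data.  Alternative literature sets can
# be supplied through the same schema.
#
# Units: disk torque rows are Nm / rad^3 / (Nm/rad) with angles in radians;
# the axial polynomial acts on compression in metres; ligament parameters a,
# c are N and b, d are percent strain; prestrain is percent.
schema: lumbocal-characteristics-v1
disk:
  rot:
    flexion:   {p1: 10.67,  p2: 0.005913, p3: -1.685}
    extension: {p1: 5.196,  p2: 0.008417, p3: 24.50}
    lateral:   {p1: 6.929,  p2: 0.001482, p3: 19.76}
    axial:     {p1: 4.399,  p2: 0.001141, p3: 42.38}
  axial_quad: 690234060.0     # N/m^2, compression-only quadratic term
  axial_lin: 659748.0         # N/m
  shear_stiffness: 260000.0   # N/m, literature placeholder (not calibrated)
  d_damp_tra: 400000.0        # N s/m
  d_damp_rot: 100.0           # Nm s
facets:
  stiffness: 12000.0          # N/m
  damping: 4000.0             # N s/m
ligaments:
  ALL: {a: 173.5,  b: -10.06, c: -26.82,  d: 5.625}
  PLL: {a: 48.12,  b: -43.97, c: -2.500,  d: 15.00}
  FL:  {a: 47.11,  b: 4.210,  c: 54.85,   d: -11.25}
  CL:  {a: 98.94,  b: 18.97,  c: -82.20,  d: 73.33}
  ISL: {a: 0.4517, b: -3.502, c: 0.0,     d: 0.02414}
  SSL:
    a: 1.218
    b: -22.97
    c: 0.0
    d: 1.369
    # separate branch used for negative strain (SSL is slack at neutral)
    neg_branch: {a: -50.49, b: -36.00, c: -0.02453, d: 4.718}
  # The intertransverse ligament was never isolated in the reduction
  # protocol, so no characteristic can be derived; it defaults to zero force.
  ITL: {a: 0.0, b: 0.0, c: 0.0, d: 1.0}
prestrains:  # percent strain at the neutral posture
  ALL: 8.0
  PLL: 10.0
  FL: 10.0
  ITL: 10.0
  CL: 10.0
  ISL: 4.0
  SSL: -6.0
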