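# Default BBB-permeability cascade (synthetic stand-in).
#
# The elliptical admissible region in (logP, TPSA) space below is an
# approximate, package-authored parameterisation of the well-known
# observation that brain-penetrant drugs cluster at moderate
# lipophilicity and low polar surface area; it is NOT a fitted
# reproduction of any published classifier's coefficients.  The range
# rules encode CNS-typical physicochemical windows (TPSA < 90 A^2,
# MW <= 600, few H-bond donors).  Edit or replace freely.
- filter_id: lipo_polarity_ellipse
  kind: ellipse
  parameters:
    center_logp: 2.5
    center_tpsa: 45.0
    axis_logp: 3.5
    axis_tpsa: 48.0
    rotation_deg: 0.0
- filter_id: tpsa_window
  kind: range_rule
  parameters:
    descriptor: tpsa
    min: 0.0
    max: 90.0
- filter_id: mw_window
  kind: range_rule
  parameters:
    descriptor: mw
    min: 0.0
    max: 600.0
- filter_id: hbd_window
  kind: range_rule
  parameters:
    descriptor: hbd
    min: 0
    max: 3
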