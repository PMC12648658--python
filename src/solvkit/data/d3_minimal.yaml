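# Minimal H/O/Mg/Cl element table in the documented schema.
# Values are rounded, D3-style magnitudes from the public zero-damping
# parameter distribution (covalent radii, sqrt(r2r4) factors, pair cutoff
# radii and CN-dependent C6 reference points in atomic units).  They are
# shipped for convenience and CLI smoke use; quantitative work should load
# a table exported from the parameter set of the target functional.
version: 1
units:
  radius: angstrom
  r0: bohr
  c6: au
  sqrt_q: bohr2
elements:
  H:  {covalent_radius: 0.32, sqrt_q: 2.007}
  O:  {covalent_radius: 0.63, sqrt_q: 2.594}
  Mg: {covalent_radius: 1.41, sqrt_q: 5.710}
  Cl: {covalent_radius: 0.99, sqrt_q: 4.170}
pairs:
  H-H:
    r0: 2.91
    c6_reference:
      - [0.00, 0.00, 7.59]
      - [0.91, 0.00, 4.72]
      - [0.91, 0.91, 3.09]
  H-O:
    r0: 2.57
    c6_reference:
      - [0.00, 0.00, 10.37]
      - [0.91, 1.89, 5.63]
      - [0.91, 2.99, 5.48]
  O-O:
    r0: 2.23
    c6_reference:
      - [0.00, 0.00, 15.51]
      - [1.89, 1.89, 10.37]
      - [2.99, 2.99, 10.09]
  H-Mg:
    r0: 3.21
    c6_reference:
      - [0.00, 0.00, 70.2]
      - [0.91, 0.00, 45.2]
      - [0.91, 9.10, 23.4]
  Mg-O:
    r0: 3.14
    c6_reference:
      - [0.00, 0.00, 101.9]
      - [1.89, 0.00, 78.5]
      - [2.99, 9.10, 41.8]
  Mg-Mg:
    r0: 3.66
    c6_reference:
      - [0.00, 0.00, 683.4]
      - [9.10, 9.10, 174.0]
  Cl-H:
    r0: 3.18
    c6_reference:
      - [0.00, 0.00, 30.0]
      - [0.00, 0.91, 21.8]
  Cl-O:
    r0: 3.10
    c6_reference:
      - [0.00, 0.00, 42.5]
      - [0.00, 2.99, 35.9]
  Cl-Mg:
    r0: 3.54
    c6_reference:
      - [0.00, 0.00, 197.5]
      - [9.10, 0.00, 103.5]
  Cl-Cl:
    r0: 3.45
    c6_reference:
      - [0.00, 0.00, 94.6]
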