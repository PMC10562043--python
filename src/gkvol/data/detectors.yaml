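# Detector active-volume geometry library (dimensions in mm).
#
# Shapes: chamber (cylindrical cavity + optional hemispherical cap -
# coaxial electrode), disk, box.  Entries marked approximate encode
# dimensions consistent with the manufacturer's nominal active volume and
# published length/diameter ratios, not a full engineering drawing; they
# may be overridden by a user-supplied library file.
detectors:
  - name: Semiflex T31010
    shape: chamber
    detector_type: ionization chamber
    cavity_radius: 2.75
    cavity_length: 3.45
    cap: true
    electrode_radius: 0.55
    electrode_length: 3.4
    nominal_volume_mm3: 125
    approximate: true
  - name: Semiflex 3D T31021
    shape: chamber
    detector_type: ionization chamber
    cavity_radius: 2.4
    cavity_length: 2.4
    cap: true
    electrode_radius: 0.4
    electrode_length: 2.3
    nominal_volume_mm3: 70
    approximate: true
  - name: PinPoint T31014
    # active length 5 mm, length-to-diameter ratio 2.5 -> diameter 2 mm
    shape: chamber
    detector_type: ionization chamber
    cavity_radius: 1.0
    cavity_length: 4.0
    cap: true
    electrode_radius: 0.15
    electrode_length: 3.8
    nominal_volume_mm3: 15
    approximate: true
  - name: PinPoint 3D T31022
    # length-to-diameter ratio 1.23, nominal 16 mm^3
    shape: chamber
    detector_type: ionization chamber
    cavity_radius: 1.34
    cavity_length: 1.9564
    cap: true
    electrode_radius: 0.15
    electrode_length: 1.9
    nominal_volume_mm3: 16
    approximate: true
  - name: Diode P T60016
    shape: disk
    detector_type: semiconductor
    radius: 0.5641896
    thickness: 0.030
    nominal_volume_mm3: 0.030
    approximate: true
  - name: Diode E T60017
    # active volume identical to Diode P T60016; only the shielding differs
    shape: disk
    detector_type: semiconductor
    radius: 0.5641896
    thickness: 0.030
    nominal_volume_mm3: 0.030
    approximate: true
  - name: microDiamond T60019
    # very thin disk, 2.2 mm diameter x 1 um
    shape: disk
    detector_type: diamond
    radius: 1.1
    thickness: 0.001
    nominal_volume_mm3: 0.004
    approximate: false
  - name: RAZOR diode
    shape: disk
    detector_type: semiconductor
    radius: 0.5641896
    thickness: 0.020
    nominal_volume_mm3: 0.020
    approximate: true
  - name: EFD 3G-pSi
    shape: disk
    detector_type: semiconductor
    radius: 1.0
    thickness: 0.0509296
    nominal_volume_mm3: 0.160
    approximate: true
  - name: EDGE detector
    shape: box
    detector_type: semiconductor
    dx: 0.8
    dy: 0.8
    dz: 0.03
    nominal_volume_mm3: 0.020
    approximate: true
  - name: RAZOR chamber
    shape: chamber
    detector_type: ionization chamber
    cavity_radius: 1.3
    cavity_length: 1.0
    cap: true
    electrode_radius: 0.2
    electrode_length: 0.9
    nominal_volume_mm3: 10
    approximate: true
  - name: IBA CC04
    # active length 3.6 mm, length-to-diameter ratio 0.9 -> diameter 4 mm
    shape: chamber
    detector_type: ionization chamber
    cavity_radius: 2.0
    cavity_length: 1.6
    cap: true
    electrode_radius: 0.25
    electrode_length: 1.4
    nominal_volume_mm3: 40
    approximate: true
  - name: Exradin W2 1x1
    # scintillator fiber 1 mm diameter x 1 mm
    shape: disk
    detector_type: plastic scintillator
    radius: 0.5
    thickness: 1.0
    nominal_volume_mm3: 0.785
    approximate: false
  - name: Exradin W2 1x3
    # scintillator fiber 1 mm diameter x 3 mm
    shape: disk
    detector_type: plastic scintillator
    radius: 0.5
    thickness: 3.0
    nominal_volume_mm3: 2.356
    approximate: false
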