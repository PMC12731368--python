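# Material registry: element weight fractions and nominal densities (g/cm^3).
# The five segmentation classes follow the standard NIST compound definitions;
# weight fractions are normalized to 1 on load.
materials:
  air:
    display_name: "Air, dry (near sea level)"
    nominal_density: 0.0012048
    composition: {C: 0.000124, N: 0.755267, O: 0.231781, Ar: 0.012827}
  paraffin:
    display_name: "Paraffin wax"
    nominal_density: 0.93
    composition: {H: 0.148605, C: 0.851395}
  adipose:
    display_name: "Adipose tissue (ICRP)"
    nominal_density: 0.92
    composition: {H: 0.119477, C: 0.637240, N: 0.007970, O: 0.232333,
                  Na: 0.000500, Mg: 0.000002, P: 0.000016, S: 0.000073,
                  Cl: 0.000119, K: 0.000032, Ca: 0.000002, Fe: 0.000002,
                  Zn: 0.000002}
  soft_tissue:
    display_name: "Tissue, soft (ICRP)"
    nominal_density: 1.00
    composition: {H: 0.104472, C: 0.232190, N: 0.024880, O: 0.630238,
                  Na: 0.001130, Mg: 0.000130, P: 0.001330, S: 0.001990,
                  Cl: 0.001340, K: 0.001990, Ca: 0.000230, Fe: 0.000050,
                  Zn: 0.000030}
  cortical_bone:
    display_name: "Bone, cortical (ICRP)"
    nominal_density: 1.85
    composition: {H: 0.047234, C: 0.144330, N: 0.041990, O: 0.446096,
                  Mg: 0.002200, P: 0.104970, S: 0.003150, Ca: 0.209930,
                  Zn: 0.000100}
  water:
    display_name: "Water, liquid"
    nominal_density: 1.00
    composition: {H: 0.111898, O: 0.888102}
  beryllium:
    display_name: "Beryllium (detector window)"
    nominal_density: 1.848
    composition: {Be: 1.0}
  silicon:
    display_name: "Silicon (detector chip)"
    nominal_density: 2.33
    composition: {Si: 1.0}

# Default HU -> material classification table (half-open intervals [low, high);
# values outside the listed domain clamp to the nearest class).
hu_table:
  - [-1000, -750, air]
  - [-750, -350, paraffin]
  - [-350, -100, adipose]
  - [-100, 250, soft_tissue]
  - [250, 2000, cortical_bone]
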