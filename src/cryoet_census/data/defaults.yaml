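# Default constants for the cryo-ET yield model and preparation planner.
# Mirrors the in-code defaults; override any subset via a user YAML.

lamella:
  width_um: 0.18                # standard FIB-milled lamella width l
  serial_lift_out_separation_um: 4.0   # block subdivision (sub-4-um possible)
  ultramicrotome_separation_um: 0.18   # contiguous diamond-knife slices

workflows:
  plunge_fib:
    freezing: plunge
    sectioning: FIB_SEM
    lamella_area_al_um2: 100.0  # 10 x 10 um; use 50 (5 x 10) for bacterial biofilm
    mill_time_tl_min: 60.0
  plunge_fib_biofilm:
    freezing: plunge
    sectioning: FIB_SEM
    lamella_area_al_um2: 50.0
    mill_time_tl_min: 60.0
  hpf_waffle:
    freezing: HPF
    sectioning: FIB_SEM
    lamella_area_al_um2: 400.0  # 20 x 20 um
    mill_time_tl_min: 150.0
  hpf_serial:
    freezing: HPF
    sectioning: serial_lift_out
    lamella_area_al_um2: 250.0  # 10 x 25 um
    mill_time_tl_min: 75.0

imaging_geometry:
  tomogram_side_um: 1.8
  pixel_size_a: 4.4
  illumination_radius_um: 2.0   # pi * r^2 = 12.6 um^2 illumination area

planner_thresholds:
  no_section_max_thickness_um: 1.0
  gallium_max_thickness_um: 10.0
  hpf_min_dimension_um: 100.0
  cryoprotectant_min_dimension_um: 200.0
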