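# Study configuration for the toy-skull comparative analyses.
# Materials in GPa (converted to MPa on load); forces in N; lengths in mm.
seed: 0
materials:
  bone: {E_GPa: 20.49, nu: 0.40}
  teeth: {E_GPa: 60.40, nu: 0.31}
# keratin constants are a study input (no printed default); a soft beak
# sheath roughly 20x more compliant than bone
keratin: {E_GPa: 1.0, nu: 0.30}
models:
  - name: skull_small
    synthetic: {length: 60, width: 30, height: 24, taper: 0.5, resolution: [6, 10, 4]}
  - name: skull_mid
    synthetic: {length: 60, width: 30, height: 24, taper: 0.5, resolution: [6, 10, 4]}
    scale: 1.5
  - name: skull_large
    synthetic: {length: 60, width: 30, height: 24, taper: 0.5, resolution: [6, 10, 4]}
    scale: 2.0
muscles:
  - {name: mAME, side: L, origin_set: m_AME_origin_L, insertion: [-8, 12, -8], force_N: 120}
  - {name: mAME, side: R, origin_set: m_AME_origin_R, insertion: [8, 12, -8], force_N: 120}
  - {name: mAMP, side: L, origin_set: m_AMP_origin_L, insertion: [-8, 10, -6], force_N: 80}
  - {name: mAMP, side: R, origin_set: m_AMP_origin_R, insertion: [8, 10, -6], force_N: 80}
base_force_N: 100
extrinsic_force_N: 100
trim_fraction: 0.05
v_ref: smallest
rhamphotheca_region: beak
output: results
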