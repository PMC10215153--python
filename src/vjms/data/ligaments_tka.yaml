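# Ligament parameters of the final TKA model: five-bundle LCL, five-bundle
# wrapped sMCL, three-bundle PCL. Stiffness in N per unit strain, reference
# strain in percent at the full-extension reference pose. Bundle prefixes:
# a = anterior, am = anterior-middle, m = middle, mp = middle-posterior,
# p = posterior. The middle PCL bundle is not listed: it is generated by
# midpoint augmentation and per-ligament stiffness calibration at run time.
toe_strain: 0.03
wrap:
  sMCL: [tibia_wrap_medial]
bundles:
  - {name: aLCL,    stiffness: 1157, ref_strain_pct: -2.66}
  - {name: amLCL,   stiffness: 1171, ref_strain_pct: 0.68}
  - {name: mLCL,    stiffness: 1175, ref_strain_pct: 4.02}
  - {name: mpLCL,   stiffness: 1172, ref_strain_pct: 2.66}
  - {name: pLCL,    stiffness: 1182, ref_strain_pct: 1.29}
  - {name: a-sMCL,  stiffness: 1469, ref_strain_pct: -4.30}
  - {name: am-sMCL, stiffness: 1603, ref_strain_pct: 0.10}
  - {name: m-sMCL,  stiffness: 1481, ref_strain_pct: 4.50}
  - {name: mp-sMCL, stiffness: 1509, ref_strain_pct: 4.47}
  - {name: p-sMCL,  stiffness: 1105, ref_strain_pct: 4.44}
  - {name: aPCL,    stiffness: 7841, ref_strain_pct: -28.6}
  - {name: pPCL,    stiffness: 1026, ref_strain_pct: -26.3}
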