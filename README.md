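# vjms — virtual joint motion simulator for TKA knees

`vjms` is a quasi-static digital twin of a 6-degree-of-freedom joint motion
simulator carrying a cruciate-retaining total knee arthroplasty (TKA). It is
built for biomechanics researchers who want to study how femoral component
rotational malalignment changes knee kinematics, ligament tensions and
compartment loading during passive laxity testing — without the implant
vendor's proprietary surfaces or a physical test machine.

The package provides:

- **synthetic geometry** — a parametric single-radius CR femoral component,
  deep-dished UHMWPE insert, tray and bone surrogates, with component
  placement by posterior condylar axis (PCA) measurement and controlled
  external malrotation (1.5° / 3.0° / 4.5° conditions);
- **a multifiber ligament system** — five-bundle sMCL (wrapping the
  proximal-medial tibia), five-bundle LCL, three-bundle PCL, with the
  quadratic-toe/linear fiber law `f(ε) = k ε²/(4 ε_t)` then `k(ε − ε_t)`,
  zero-force lengths back-computed from published reference strains via
  `ε_r = (l_r − l_0)/l_0 × 100 %`, midpoint bundle augmentation and
  force-conserving stiffness calibration;
- **component-on-insert contact** by inferior–superior penetration testing
  with a conservative penalty law and medial/lateral compartment
  decomposition;
- **a mixed force/displacement equilibrium solver** (femur: flexion
  prescribed, ad–abduction force-controlled; tibia: three translations and
  axial rotation force-controlled) converging to 0.5 N / 50 N·mm;
- **Grood–Suntay kinematics** (varus +, tibial external rotation +,
  posterior translation −) and laxity computation;
- **the full malrotation study**: 3 conditions × 5 flexion angles ×
  {neutral flexion, 100 N posterior drawer, ±8 N·m varus–valgus,
  ±4 N·m internal–external}.

## Worked example

```python
from vjms import (make_knee_geometry, place_component, build_ligament_set,
                  KneeModel, neutral_flexion, ramped_solve)

geom = place_component(make_knee_geometry(), "external")   # 4.5 deg ext.
model = KneeModel(geom, build_ligament_set(geom))

neutral = neutral_flexion(model, [0, 15, 30, 60, 90])
at90 = neutral[-1]
print(f"VV {at90.jcs.VV:+.2f} deg, sMCL "
      f"{sum(t for b, t in at90.tensions.items() if 'sMCL' in b):.1f} N, "
      f"medial {at90.contact.medial_force:.0f} N / "
      f"lateral {at90.contact.lateral_force:.0f} N")

varus = ramped_solve(model, 90.0, {"femur_aa": -8000.0}, at90.state)
print(f"varus laxity {abs(varus.jcs.VV - at90.jcs.VV):.2f} deg")
```

prints

```
VV +2.01 deg, sMCL 60.9 N, medial 63 N / lateral 59 N
varus laxity 2.30 deg
```

i.e. the externally over-rotated component leaves the knee about 2° varus
at 90° flexion with reduced superficial-MCL tension — the directional
signature of external femoral malrotation — and a 2.3° varus laxity under
8 N·m. The same machinery runs from the shell:

```bash
vjms geometry --condition external --out geom/        # STL per part
vjms simulate --condition baseline --test varus --flexion 0,30,90
vjms study --out results/                             # the full experiment
```

`vjms study` writes `kinematics.csv`, `laxity.csv`, `tensions.csv`,
`compartments.csv`, `deltas.csv` and a JSON summary.

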