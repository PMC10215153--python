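"""The femoral-malrotation laxity study.

Orchestrates the full factorial experiment: three malrotation conditions
(component externally rotated 1.5 / 3.0 / 4.5 degrees from the femoral
posterior condylar axis) x {neutral flexion + posterior drawer, varus,
valgus, internal and external rotation laxity tests} x five flexion angles
(0, 15, 30, 60, 90 degrees). Loads follow the laxity protocol: 100 N
posterior force, +/-8 N*m varus-valgus torque, +/-4 N*m axial torque, with
every unprescribed DOF load-controlled at zero.

Outputs are tidy tables: Grood-Suntay kinematics per solved pose, laxities
(absolute loaded-minus-neutral differences), per-bundle tensions, and
medial/lateral compartment compressive forces, plus deltas relative to the
baseline condition's neutral-flexion trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .equilibrium import _ANGULAR, KneeModel, neutral_flexion, ramped_solve
from .geometry import CONDITIONS, ImplantParams, make_knee_geometry, place_component
from .jcs import DOF_NAMES, laxity, relative_to_baseline
from .ligaments import build_ligament_set, load_parameter_table

__all__ = [
    "StudyConfig",
    "StudyResults",
    "LAXITY_TESTS",
    "run_study",
    "compartment_deltas",
    "laxity_spread",
    "summary_metrics",
    "write_results",
]


class StudyError(RuntimeError):
    pass


#: laxity test definitions: applied generalized loads (N / N*mm, simulator
#: sign conventions) and the Grood-Suntay DOF the test reads out
LAXITY_TESTS: dict[str, tuple[dict, str]] = {
    "posterior": ({"tibia_ap": -100.0}, "AP"),
    "varus": ({"femur_aa": -8000.0}, "VV"),
    "valgus": ({"femur_aa": 8000.0}, "VV"),
    "internal": ({"tibia_ie": 4000.0}, "IE"),
    "external": ({"tibia_ie": -4000.0}, "IE"),
}


@dataclass
class StudyConfig:
    flexion_angles: tuple = (0.0, 15.0, 30.0, 60.0, 90.0)
    posterior_force: float = 100.0      # N
    vv_torque: float = 8000.0           # N*mm
    ie_torque: float = 4000.0           # N*mm
    conditions: tuple = ("internal", "baseline", "external")
    tests: tuple = ("posterior", "varus", "valgus", "internal", "external")
    implant_params: ImplantParams = field(default_factory=ImplantParams)
    ligament_table: str | None = None   # None = packaged Table-1 file
    output_dir: str | None = None

    def __post_init__(self):
        angles = list(self.flexion_angles)
        if not angles or any(b < a for a, b in zip(angles, angles[1:])):
            raise StudyError("flexion angles must be non-empty ascending")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise StudyError(f"unknown condition {c!r}")

    def test_targets(self, test: str) -> dict:
        base = {
            "posterior": {"tibia_ap": -self.posterior_force},
            "varus": {"femur_aa": -self.vv_torque},
            "valgus": {"femur_aa": self.vv_torque},
            "internal": {"tibia_ie": self.ie_torque},
            "external": {"tibia_ie": -self.ie_torque},
        }
        return base[test]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "implant_params" in raw:
            raw["implant_params"] = ImplantParams(**raw["implant_params"])
        for key in ("flexion_angles", "conditions", "tests"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class StudyResults:
    kinematics: pd.DataFrame
    laxity: pd.DataFrame
    tensions: pd.DataFrame
    compartments: pd.DataFrame
    deltas: pd.DataFrame
    config: StudyConfig
    n_solves: int


def _record(rows_kin, rows_ten, rows_comp, condition, test, angle, sol):
    j = sol.jcs
    res_f = max((abs(v) for k, v in sol.residuals.items()
                 if k not in _ANGULAR), default=0.0)
    res_m = max((abs(v) for k, v in sol.residuals.items()
                 if k in _ANGULAR), default=0.0)
    rows_kin.append({"condition": condition, "test": test,
                     "flexion_deg": angle,
                     **{d: j[d] for d in DOF_NAMES},
                     "residual_force_n": res_f,
                     "residual_moment_nmm": res_m,
                     "converged": sol.converged})
    for bundle, t in sol.tensions.items():
        rows_ten.append({"condition": condition, "test": test,
                         "flexion_deg": angle, "bundle": bundle,
                         "tension_n": t})
    c = sol.contact
    rows_comp.append({"condition": condition, "test": test,
                      "flexion_deg": angle,
                      "net_compression_n": c.net_compression,
                      "medial_n": c.medial_force,
                      "lateral_n": c.lateral_force,
                      "max_penetration_mm": c.max_penetration})


def run_study(config: StudyConfig | None = None) -> StudyResults:
    """Run the full malrotation study and return its result tables.

    Geometry is built once; the ligament model is calibrated once (the
    conditions share bones and insert, only the femoral component moves)
    and reused. Every laxity solve is seeded from the neutral equilibrium
    at its flexion angle with the load ramped in four increments.
    """
    config = config or StudyConfig()
    base = make_knee_geometry(config.implant_params)
    table = load_parameter_table(config.ligament_table)
    lig_set = build_ligament_set(base, table)

    rows_kin, rows_ten, rows_comp, rows_lax = [], [], [], []
    n_solves = 0
    for condition in config.conditions:
        geom = place_component(base, condition)
        model = KneeModel(geom, lig_set)
        try:
            neutrals = neutral_flexion(model, config.flexion_angles)
        except Exception as exc:
            raise StudyError(
                f"neutral flexion failed for condition {condition!r}: {exc}"
            ) from exc
        for angle, nsol in zip(config.flexion_angles, neutrals):
            n_solves += 1
            _record(rows_kin, rows_ten, rows_comp, condition, "neutral",
                    angle, nsol)
            for test in config.tests:
                targets = config.test_targets(test)
                sol = ramped_solve(model, float(angle), targets, nsol.state)
                n_solves += 1
                if not sol.converged:
                    warnings.warn(
                        f"{condition}/{test}@{angle} deg did not converge "
                        f"(residuals {sol.residuals}); cell flagged")
                _record(rows_kin, rows_ten, rows_comp, condition, test,
                        angle, sol)
                dof = LAXITY_TESTS[test][1]
                rows_lax.append({
                    "condition": condition, "test": test,
                    "flexion_deg": angle, "dof": dof,
                    "laxity": laxity(nsol.jcs, sol.jcs, dof),
                    "converged": sol.converged,
                })

    kin = pd.DataFrame(rows_kin)
    results = StudyResults(
        kinematics=kin,
        laxity=pd.DataFrame(rows_lax),
        tensions=pd.DataFrame(rows_ten),
        compartments=pd.DataFrame(rows_comp),
        deltas=relative_to_baseline(kin) if "baseline" in config.conditions
        else pd.DataFrame(),
        config=config,
        n_solves=n_solves,
    )
    if config.output_dir:
        write_results(results, config.output_dir)
    return results


def compartment_deltas(results: StudyResults,
                       test: str = "neutral") -> pd.DataFrame:
    """Medial/lateral compressive-force changes vs the baseline condition.

    Per flexion angle and condition: (condition force - baseline force)
    for each compartment during the given test.
    """
    comp = results.compartments
    comp = comp[comp["test"] == test]
    base = comp[comp["condition"] == "baseline"]
    if base.empty:
        raise StudyError("baseline condition missing")
    ref = base.set_index("flexion_deg")[["medial_n", "lateral_n",
                                         "net_compression_n"]]
    out = comp.copy()
    for col, new in (("medial_n", "medial_delta_n"),
                     ("lateral_n", "lateral_delta_n"),
                     ("net_compression_n", "net_delta_n")):
        out[new] = (comp[col].to_numpy()
                    - ref[col].reindex(comp["flexion_deg"]).to_numpy())
    return out[["condition", "flexion_deg", "medial_delta_n",
                "lateral_delta_n", "net_delta_n"]]


def laxity_spread(results: StudyResults, dof: str) -> pd.DataFrame:
    """Across-condition spread (max - min) of laxity per angle and test.

    Rows flagged non-converged are excluded with a warning. The overall
    maximum is ``laxity_spread(...)["spread"].max()``.
    """
    lax = results.laxity
    lax = lax[lax["dof"] == dof]
    bad = lax[~lax["converged"]]
    if len(bad):
        warnings.warn(f"excluding {len(bad)} non-converged laxity cells")
        lax = lax[lax["converged"]]
    grouped = lax.groupby(["test", "flexion_deg"])["laxity"]
    out = (grouped.max() - grouped.min()).reset_index(name="spread")
    return out


def neutral_ap_spread(results: StudyResults) -> pd.DataFrame:
    """Across-condition spread of the neutral-flexion AP position."""
    kin = results.kinematics
    kin = kin[kin["test"] == "neutral"]
    grouped = kin.groupby("flexion_deg")["AP"]
    return (grouped.max() - grouped.min()).reset_index(name="spread")


def summary_metrics(results: StudyResults) -> dict:
    """Headline scalar outcomes of the study (mm / degrees)."""
    lax = results.laxity[results.laxity["converged"]]
    post = lax[lax["test"] == "posterior"]["laxity"]
    return {
        "max_posterior_laxity_mm": float(post.max()),
        "max_neutral_ap_spread_mm": float(
            neutral_ap_spread(results)["spread"].max()),
        "max_vv_laxity_spread_deg": float(
            laxity_spread(results, "VV")["spread"].max()),
        "max_ie_laxity_spread_deg": float(
            laxity_spread(results, "IE")["spread"].max()),
    }


def write_results(results: StudyResults, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (("kinematics", results.kinematics),
                     ("laxity", results.laxity),
                     ("tensions", results.tensions),
                     ("compartments", results.compartments),
                     ("deltas", results.deltas)):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
    return written
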