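"""Model/Results interface for a single patellofemoral contact analysis.

:class:`PatellofemoralModel` bundles a knee geometry, a flexion angle, the
material law and the solver configuration; ``fit()`` performs the
quasi-static equilibrium solve and returns a
:class:`PatellofemoralResults` carrying the solution, stress and alignment
metrics, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem.materials import MaterialParams
from .fem.tetmesh import TetMesh, extrude_cartilage, scale_thickness
from .geometry.knee import KneeModel, build_knee
from .loading import LoadCase, build_load_case
from .metrics import (
    AlignmentMetrics,
    StressMetrics,
    alignment_metrics,
    stress_metrics,
)
from .solver import SolverSettings, Solution, residual_report, solve_quasistatic


class PatellofemoralModel:
    """Quasi-static patellofemoral contact model at one flexion angle.

    Parameters
    ----------
    knee : KneeModel
        Surface geometry, thickness maps and landmarks.
    theta : float
        Knee flexion angle in degrees (30-75).
    material : MaterialParams, optional
        Cartilage constitutive parameters (default E=5 MPa, nu=0.47).
    loading : dict, optional
        Loading-protocol overrides (muscle total, direction table,
        prestrain, stiffnesses, start pose).
    settings : SolverSettings, optional
    layers : int
        Tetrahedral layers through the cartilage thickness.
    thickness_factor : float
        Uniform cartilage thickness scaling (sensitivity envelope 0.6-1.4).
    """

    def __init__(
        self,
        knee: KneeModel,
        theta: float,
        material: MaterialParams | None = None,
        loading: dict | None = None,
        settings: SolverSettings | None = None,
        layers: int = 3,
        thickness_factor: float = 1.0,
    ):
        self.knee = knee
        self.theta = float(theta)
        self.material = material or MaterialParams()
        self.loading = dict(loading or {})
        self.settings = settings or SolverSettings()
        self.layers = int(layers)
        self.thickness_factor = float(thickness_factor)
        self._meshes: tuple[TetMesh, TetMesh] | None = None

    @classmethod
    def from_preset(
        cls,
        preset: str,
        theta: float,
        overrides: dict | None = None,
        seed: int = 0,
        resolution: dict | None = None,
        **kwargs,
    ) -> "PatellofemoralModel":
        knee = build_knee(preset, overrides=overrides, seed=seed, resolution=resolution)
        return cls(knee, theta, **kwargs)

    @property
    def meshes(self) -> tuple[TetMesh, TetMesh]:
        """(femoral, patellar) cartilage tet meshes, built lazily."""
        if self._meshes is None:
            ft = self.knee.femur_thickness
            pt = self.knee.patella_thickness
            if self.thickness_factor != 1.0:
                ft = scale_thickness(ft, self.thickness_factor)
                pt = scale_thickness(pt, self.thickness_factor)
            self._meshes = (
                extrude_cartilage(
                    self.knee.femur_surface, ft, layers=self.layers, part="femur"
                ),
                extrude_cartilage(
                    self.knee.patella_surface, pt, layers=self.layers, part="patella"
                ),
            )
        return self._meshes

    def load_case(self) -> LoadCase:
        return build_load_case(self.knee, self.theta, self.loading)

    def fit(self) -> "PatellofemoralResults":
        """Solve the quasi-static equilibrium and post-process."""
        case = self.load_case()
        sol = solve_quasistatic(case, self.meshes, self.material, self.settings)
        return PatellofemoralResults(self, case, sol)


@dataclass
class PatellofemoralResults:
    """Solved state with stress, area and alignment metrics."""

    model: PatellofemoralModel
    case: LoadCase
    solution: Solution
    _stress: StressMetrics | None = field(default=None, repr=False)

    @property
    def converged(self) -> bool:
        return self.solution.converged and self.solution.status == "converged"

    @property
    def stress(self) -> StressMetrics:
        if self._stress is None:
            fm, pm = self.model.meshes
            self._stress = stress_metrics(
                self.solution, fm, pm, self.model.material
            )
        return self._stress

    @property
    def alignment(self) -> AlignmentMetrics:
        return alignment_metrics(self.model.knee, self.solution)

    def force_balance(self) -> dict:
        return residual_report(self.solution, self.case)

    def summary(self) -> str:
        """Plain-text summary table of the solve and its output measures."""
        k = self.model.knee
        lines = [
            "Patellofemoral contact analysis",
            "=" * 46,
            f"{'preset':<28}{k.meta.get('preset', 'custom'):>18}",
            f"{'flexion angle [deg]':<28}{self.model.theta:>18.1f}",
            f"{'status':<28}{self.solution.status:>18}",
            f"{'iterations':<28}{self.solution.iterations:>18d}",
            f"{'residual / applied':<28}"
            f"{self.force_balance()['residual_fraction_of_applied']:>18.2e}",
            "-" * 46,
        ]
        if self.converged:
            s = self.stress
            a = self.alignment
            mean_p = "n/a" if s.mean_pressure is None else f"{s.mean_pressure:.3f}"
            lines += [
                f"{'peak contact pressure [MPa]':<32}{s.peak_pressure:>14.3f}",
                f"{'mean contact pressure [MPa]':<32}{mean_p:>14}",
                f"{'contact area [mm^2]':<32}{s.contact_area:>14.1f}",
                f"{'peak VMes patella [MPa]':<32}{s.peak_vmes_patella:>14.3f}",
                f"{'peak VMes trochlea [MPa]':<32}{s.peak_vmes_trochlea:>14.3f}",
                f"{'patellar tilt [deg]':<32}{a.patellar_tilt:>14.1f}",
                f"{'bisect offset [%]':<32}{a.bisect_offset:>14.1f}",
                f"{'TT-TG [mm]':<32}{a.tt_tg:>14.1f}",
            ]
        else:
            lines.append("solve did not converge; stress metrics withheld")
        lines.append("=" * 46)
        return "\n".join(lines)
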