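"""Axial cross-section profiles of the trochlear groove.

Each axial station of the distal femur is described in its own 2D plane
(x lateral along the posterior condylar baseline BL, y anterior).  The
anterior arc carries the morphology that matters clinically: the most
prominent lateral (LC) and medial (MC) condylar points and the sulcus S.
Groove depth is the posterior distance of S behind the LC–MC chord;
a non-positive depth is a flat or convex (dysplastic) trochlea.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from shapely.geometry import LinearRing

from .surface import GeometryError


@dataclass
class AxialProfile:
    """One axial station of the trochlea.

    ``contour`` is an ordered simple polygon (counter-clockwise, implicitly
    closed): columns ``0 .. n_arc-1`` run across the anterior arc from the
    medial to the lateral edge with strictly increasing x, the remaining
    columns close the section around the posterior condyles.
    """

    z: float
    contour: np.ndarray          # (C, 2)
    sulcus_index: int
    lc_index: int
    mc_index: int
    baseline: np.ndarray         # (2,), unit vector along BL (+x lateral)

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        n = np.linalg.norm(self.baseline)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise GeometryError("baseline must be a unit vector")
        if not (self.mc_index < self.sulcus_index < self.lc_index):
            raise GeometryError(
                "sulcus must lie strictly between the medial and lateral "
                "condylar points along the anterior arc"
            )

    @property
    def sulcus(self) -> np.ndarray:
        return self.contour[self.sulcus_index]

    @property
    def lc(self) -> np.ndarray:
        return self.contour[self.lc_index]

    @property
    def mc(self) -> np.ndarray:
        return self.contour[self.mc_index]

    def groove_depth(self) -> float:
        """Signed depth of S behind the LC–MC chord (+ = grooved, − = convex)."""
        lc, mc, s = self.lc, self.mc, self.sulcus
        t = (s[0] - mc[0]) / (lc[0] - mc[0])
        y_chord = mc[1] + t * (lc[1] - mc[1])
        return float(y_chord - s[1])

    def is_simple(self) -> bool:
        return bool(LinearRing(self.contour).is_simple)


def anterior_arc(
    x_mc: float,
    y_mc: float,
    x_lc: float,
    y_lc: float,
    depth: float,
    x_sulcus: float,
    sulcus_angle_deg: float,
    x_edge_m: float,
    y_edge_m: float,
    x_edge_l: float,
    y_edge_l: float,
    x_samples: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Build the anterior arc y(x) of one station through its control points.

    The arc is a monotone piecewise-cubic (PCHIP) through the medial edge,
    MC, optional groove shoulder points, the sulcus, LC and the lateral
    edge.  ``depth`` is the signed groove depth; the shoulder points are
    placed from the sulcus half-angle and only used for clearly grooved
    sections.  Returns (y values on ``x_samples``, sulcus y).
    """
    t = (x_sulcus - x_mc) / (x_lc - x_mc)
    y_chord = y_mc + t * (y_lc - y_mc)
    y_s = y_chord - depth

    xs = [x_edge_m, x_mc]
    ys = [y_edge_m, y_mc]
    if depth > 0.75:
        half = np.radians(max(min(sulcus_angle_deg, 175.0), 90.0) / 2.0)
        s_l = 0.35 * (x_lc - x_sulcus)
        s_m = 0.35 * (x_sulcus - x_mc)
        y_sh_m = min(y_s + s_m / np.tan(half), y_chord - 0.15 * depth)
        y_sh_l = min(y_s + s_l / np.tan(half), y_chord - 0.15 * depth)
        xs += [x_sulcus - s_m, x_sulcus, x_sulcus + s_l]
        ys += [y_sh_m, y_s, y_sh_l]
    else:
        xs += [x_sulcus]
        ys += [y_s]
    xs += [x_lc, x_edge_l]
    ys += [y_lc, y_edge_l]
    f = PchipInterpolator(np.asarray(xs), np.asarray(ys))
    return np.asarray(f(x_samples)), float(y_s)
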